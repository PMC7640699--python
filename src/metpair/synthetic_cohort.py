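"""Synthetic paired primary/metastasis cohorts with known ground truth.

Each simulated patient carries a primary tumor, a distant metastasis and
a matched normal, generated from an explicit clone tree:

* the trunk clone has CCF 1 in both tumor samples; subclones occupy
  predefined CCF slots chosen so that (a) sibling CCFs never exceed
  their parent's (pigeonhole-consistent by construction) and (b) any two
  clusters are at least 0.2 apart in joint CCF space, the regime where
  subclonal reconstruction from 200x exome data is expected to work;
* monoclonal seeding puts every subclone in exactly one sample;
  polyclonal seeding forces one subclone to appreciable CCF (>= 0.2) in
  both samples;
* alt read counts are Binomial(depth, expected VAF) with
  expected VAF = purity * m * CCF / (purity * CN_t + 2 * (1 - purity));
* copy-number segments emit the purity-mixed observed ratio
  r = purity * CN_t / 2 + (1 - purity), so the standard purity
  adjustment (r - 1)/purity + 1 recovers CN_t / 2 exactly;
* trinucleotide contexts are sampled from each clone's signature mix
  over the 96 channels (no reference genome needed); the trunk mix is
  enriched for the first signature by a configurable delta relative to
  private clones, emulating an early mutational process;
* allelic-imbalance regions emit phased-site deviations that point at
  the event haplotype with the configured concordance (0.5 elsewhere);
* metastasis immune-gene expression is scaled down by a configured
  factor, and a subset of genes carries promoter methylation
  anti-correlated with expression.

Everything is deterministic given the seed; a cohort derives per-patient
seeds from the master seed via ``numpy.random.SeedSequence``.

The toy genome has 10 chromosomes of 10 Mb, 100 evenly spaced 5-kb genes
per chromosome, and 4 copy-number segment slots of 2.5 Mb per
chromosome. Gains use CN 4 and losses CN 0 by default: at the default
purity of 0.6 these are the aberrations whose *unadjusted* ratios pass
the +/- log2(1.5) thresholds and therefore trigger the conditional
purity adjustment downstream; single-copy events at moderate purity are
invisible to that rule by design.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from metpair.io_formats import (
    CNSegmentRecord,
    MutationRecord,
    PhasedSiteRecord,
    SampleMeta,
    write_matrix,
    write_mutations,
    write_phased_sites,
    write_sample_meta,
    write_segments,
)
from metpair.signature_fit import CHANNELS_96

N_CHROM = 10
CHROM_LEN = 10_000_000
SEG_PER_CHROM = 4
SEG_LEN = CHROM_LEN // SEG_PER_CHROM
GENES_PER_CHROM = 100
GENE_LEN = 5_000
GENE_SPACING = CHROM_LEN // GENES_PER_CHROM

#: CCF slots for private subclones within one sample (>= 0.2 apart, sum < 1)
PRIVATE_SLOTS = ((0.20, 0.30), (0.50, 0.65))
#: CCF slot (per sample) for the shared subclone in polyclonal seeding
SHARED_SLOT = (0.25, 0.45)

_EFFECT_CHOICES = ("missense", "synonymous", "stop-gain", "splicing",
                   "frameshift-indel", "other")
_EFFECT_PROBS = (0.55, 0.25, 0.06, 0.04, 0.0, 0.10)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated patient (or a cohort).

    Defaults emulate a 200x tumor exome at purity 0.6 with four clones of
    about 40 mutations each.
    """

    n_clones: int = 4
    mutations_per_clone: float = 40.0
    depth: int = 200
    depth_poisson: bool = False
    normal_depth: int = 100
    purity: float = 0.6
    seeding_mode: str = "monoclonal"  # monoclonal | polyclonal | mixed
    ai_concordance: float = 0.85
    immune_effect: float = 0.5
    trunk_sig_delta: float = 0.4
    n_signatures: int = 5
    include_ai: bool = True
    include_expression: bool = True
    n_expression_genes: int = 300
    n_immune_genes: int = 40
    n_methylation_genes: int = 120
    n_meth_regulated: int = 40
    sites_per_chrom: int = 300
    site_depth: int = 50
    ai_chroms: int = 3
    scna_trunk: int = 6
    scna_primary: int = 2
    scna_metastasis: int = 2
    gain_cn: int = 4
    loss_cn: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        section = data.get("simulate", data)
        unknown = set(section) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**section)


@dataclass
class CloneNode:
    clone_id: int
    parent_id: int | None
    ccf_by_sample: dict[str, float]
    n_mutations: int
    signature_mix: np.ndarray


@dataclass
class GroundTruth:
    seeding_mode: str
    clones: list[CloneNode]
    clone_of_mutation: dict
    trunk_fraction: float
    category_mixes: dict[str, np.ndarray]
    scna_calls: dict[str, dict[str, str]]
    scna_trunk_fraction: float
    ai_regions: dict[str, list[tuple[str, int, int]]]
    immune_effect: float


@dataclass
class PatientBundle:
    patient_id: str
    meta: list[SampleMeta]
    mutations: list[MutationRecord]
    segments: list[CNSegmentRecord]
    phased_sites: dict[str, list[PhasedSiteRecord]] = field(default_factory=dict)
    expression: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None

    @property
    def primary_id(self) -> str:
        return next(m.sample_id for m in self.meta if m.role == "primary")

    @property
    def metastasis_id(self) -> str:
        return next(m.sample_id for m in self.meta if m.role == "metastasis")

    def mutations_of(self, sample_id: str) -> list[MutationRecord]:
        return [m for m in self.mutations if m.sample_id == sample_id]


def toy_gene_model() -> pd.DataFrame:
    """BED-like 1000-gene model on the toy genome (1-based inclusive)."""
    rows = []
    g = 0
    for c in range(N_CHROM):
        for j in range(GENES_PER_CHROM):
            start = j * GENE_SPACING + 50_001
            rows.append({
                "gene": f"G{g:04d}", "chrom": str(c + 1),
                "start": start, "end": start + GENE_LEN - 1,
            })
            g += 1
    return pd.DataFrame(rows)


def synthetic_signatures(k: int = 5, seed: int = 20240) -> pd.DataFrame:
    """A 96 x k column-stochastic synthetic signature matrix.

    Sparse Dirichlet draws give well-separated synthetic spectra; this is
    a stand-in for a user-supplied reference signature matrix (e.g. the
    30 COSMIC v2 signatures), used by the generator and the tests.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for i in range(k):
        cols[f"SYN{i + 1}"] = rng.dirichlet(np.full(96, 0.15))
    return pd.DataFrame(cols, index=list(CHANNELS_96))


def immune_panel(n: int = 40) -> list[str]:
    """Placeholder immune-gene panel for synthetic data and tests (the
    real panel of cytolytic/HLA/IFN-gamma/chemokine/adhesion genes is a
    user input)."""
    return [f"IMM{i + 1:03d}" for i in range(n)]


# ------------------------------------------------------------- clone tree

def _make_clone_tree(cfg: SimConfig, mode: str, rng: np.random.Generator,
                     primary_id: str, met_id: str,
                     signatures: pd.DataFrame) -> list[CloneNode]:
    n_sub = cfg.n_clones - 1
    if cfg.n_clones < 2:
        raise ConfigError("need at least 2 clones (trunk + 1 subclone)")
    if mode == "polyclonal" and n_sub < 2:
        raise ConfigError("polyclonal mode needs at least 2 non-trunk clones")
    k = signatures.shape[1]
    base = np.full(k, (1.0 - 0.1) / (k - 1))
    base[0] = 0.1
    trunk_mix = base.copy()
    trunk_mix[0] += cfg.trunk_sig_delta
    trunk_mix[1:] *= (1.0 - trunk_mix[0]) / trunk_mix[1:].sum()

    def n_mut():
        return max(1, int(rng.poisson(cfg.mutations_per_clone)))

    clones = [CloneNode(0, None, {primary_id: 1.0, met_id: 1.0},
                        n_mut(), trunk_mix)]
    slots_used = {primary_id: 0, met_id: 0}

    def add_private(host: str, other: str, cid: int):
        idx = slots_used[host]
        if idx >= len(PRIVATE_SLOTS):
            raise ConfigError(
                f"too many private subclones for sample {host} "
                f"(max {len(PRIVATE_SLOTS)} per sample)")
        lo, hi = PRIVATE_SLOTS[idx]
        slots_used[host] += 1
        clones.append(CloneNode(
            cid, 0, {host: float(rng.uniform(lo, hi)), other: 0.0},
            n_mut(), base))

    hosts = [primary_id, met_id]
    cid = 1
    if mode == "polyclonal":
        lo, hi = SHARED_SLOT
        clones.append(CloneNode(
            cid, 0,
            {primary_id: float(rng.uniform(lo, hi)),
             met_id: float(rng.uniform(lo, hi))},
            n_mut(), base))
        cid += 1
        # with the shared clone in play, at most one private fits per sample
        if n_sub - 1 > 2:
            raise ConfigError("polyclonal mode supports at most 3 subclones")
        for i in range(n_sub - 1):
            host = hosts[i % 2]
            other = hosts[1 - i % 2]
            lo, hi = PRIVATE_SLOTS[0]
            clones.append(CloneNode(
                cid, 0, {host: float(rng.uniform(lo, hi)), other: 0.0},
                n_mut(), base))
            cid += 1
    else:
        order = [hosts[i % 2] for i in range(n_sub)]
        for host in order:
            add_private(host, hosts[1 - hosts.index(host)], cid)
            cid += 1
    return clones


# ----------------------------------------------------------------- SCNA

def _simulate_scna(cfg: SimConfig, rng: np.random.Generator,
                   primary_id: str, met_id: str):
    """Choose segment slots for trunk / primary / metastasis events and
    return per-sample CN arrays over the 40 segment slots."""
    n_slots = N_CHROM * SEG_PER_CHROM
    n_events = cfg.scna_trunk + cfg.scna_primary + cfg.scna_metastasis
    if n_events > n_slots:
        raise ConfigError("more SCNA events than segment slots")
    slots = rng.choice(n_slots, size=n_events, replace=False)
    cn = {primary_id: np.full(n_slots, 2, dtype=int),
          met_id: np.full(n_slots, 2, dtype=int)}
    truth_label = {}
    i = 0
    for j in range(cfg.scna_trunk):
        cnv = cfg.gain_cn if j % 2 == 0 else cfg.loss_cn
        cn[primary_id][slots[i]] = cnv
        cn[met_id][slots[i]] = cnv
        truth_label[int(slots[i])] = "trunk"
        i += 1
    for j in range(cfg.scna_primary):
        cn[primary_id][slots[i]] = cfg.gain_cn if j % 2 == 0 else cfg.loss_cn
        truth_label[int(slots[i])] = "primary_specific"
        i += 1
    for j in range(cfg.scna_metastasis):
        cn[met_id][slots[i]] = cfg.gain_cn if j % 2 == 0 else cfg.loss_cn
        truth_label[int(slots[i])] = "metastasis_specific"
        i += 1
    return cn, truth_label


def _segments_from_cn(cn: np.ndarray, sample_id: str,
                      purity: float) -> list[CNSegmentRecord]:
    segs = []
    for slot in range(cn.size):
        chrom = slot // SEG_PER_CHROM + 1
        offset = (slot % SEG_PER_CHROM) * SEG_LEN
        r = purity * cn[slot] / 2.0 + (1.0 - purity)
        segs.append(CNSegmentRecord(
            chrom=str(chrom), start=offset + 1, end=offset + SEG_LEN,
            log2_ratio=float(np.log2(r)), sample_id=sample_id))
    return segs


def _slot_of(chrom: str, pos: int) -> int:
    return (int(chrom) - 1) * SEG_PER_CHROM + (pos - 1) // SEG_LEN


# ------------------------------------------------------------- mutations

def _simulate_mutations(cfg, rng, clones, cn_by_sample, gene_model,
                        signatures, primary_id, met_id):
    sig = signatures.values  # 96 x K
    gene_lookup = {}
    for row in gene_model.itertuples(index=False):
        gene_lookup[(row.chrom, row.start)] = row
    records: list[MutationRecord] = []
    clone_of: dict[tuple, int] = {}
    used_pos: set[tuple] = set()
    for clone in clones:
        p96 = sig @ clone.signature_mix
        p96 = p96 / p96.sum()
        channel_idx = rng.choice(96, size=clone.n_mutations, p=p96)
        for ci in channel_idx:
            chrom, pos = _draw_position(rng, cn_by_sample, used_pos)
            channel = CHANNELS_96[ci]
            ref, alt = channel[2], channel[4]
            context = channel[0] + ref + channel[6]
            gene = _gene_at(chrom, pos)
            effect = str(rng.choice(_EFFECT_CHOICES, p=_EFFECT_PROBS))
            key = (chrom, pos, ref, alt)
            clone_of[key] = clone.clone_id
            slot = _slot_of(chrom, pos)
            # truncal mutations on a gained segment may predate the gain
            # and sit on the duplicated (major) allele; mutations arising
            # after the gain (subclones) sit on a single copy
            m_gain = None
            for sid in (primary_id, met_id):
                cn_s = int(cn_by_sample[sid][slot])
                if cn_s > 2 and clone.parent_id is None:
                    if m_gain is None:
                        m_gain = int(rng.choice([1, cn_s - 1]))
                    m_s = m_gain
                else:
                    m_s = 1
                ccf = clone.ccf_by_sample[sid]
                vaf = (cfg.purity * m_s * ccf
                       / (cfg.purity * cn_s + 2 * (1 - cfg.purity)))
                depth = (int(rng.poisson(cfg.depth)) if cfg.depth_poisson
                         else cfg.depth)
                depth = max(depth, 1)
                t_alt = int(rng.binomial(depth, min(vaf, 1.0)))
                records.append(MutationRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sid,
                    t_depth=depth, t_alt=t_alt,
                    n_depth=cfg.normal_depth, n_alt=0,
                    pop_af=0.0, gene=gene, effect=effect, context=context))
    return records, clone_of


def _draw_position(rng, cn_by_sample, used_pos):
    for _ in range(1000):
        chrom = str(int(rng.integers(1, N_CHROM + 1)))
        pos = int(rng.integers(1, CHROM_LEN + 1))
        slot = _slot_of(chrom, pos)
        if any(cn[slot] == 0 for cn in cn_by_sample.values()):
            continue  # no copies left to mutate on
        if (chrom, pos) in used_pos:
            continue
        used_pos.add((chrom, pos))
        return chrom, pos
    raise RuntimeError("could not place mutation")


def _gene_at(chrom: str, pos: int) -> str:
    j = (pos - 50_001) // GENE_SPACING
    if j < 0 or j >= GENES_PER_CHROM:
        return ""
    start = j * GENE_SPACING + 50_001
    if start <= pos <= start + GENE_LEN - 1:
        g = (int(chrom) - 1) * GENES_PER_CHROM + j
        return f"G{g:04d}"
    return ""


# ------------------------------------------------------------------- AI

def _simulate_sites(cfg, rng, sample_id, affected_regions):
    """Phased sites for one sample; ``affected_regions`` is a list of
    (chrom, first_site_index, last_site_index) with AI in this sample."""
    sites = []
    for c in range(cfg.ai_chroms):
        chrom = str(c + 1)
        spacing = CHROM_LEN // (cfg.sites_per_chrom + 1)
        region = next(((lo, hi) for ch, lo, hi in affected_regions
                       if ch == chrom), None)
        haps = rng.integers(0, 2, size=cfg.sites_per_chrom)
        for i in range(cfg.sites_per_chrom):
            pos = (i + 1) * spacing
            in_ai = region is not None and region[0] <= i <= region[1]
            if in_ai:
                toward0 = rng.random() < cfg.ai_concordance
                major = int(rng.binomial(cfg.site_depth, 0.65))
                major = max(major, cfg.site_depth // 2 + 1)
                hap0_count = major if toward0 else cfg.site_depth - major
            else:
                hap0_count = int(rng.binomial(cfg.site_depth, 0.5))
            hap = int(haps[i])
            ref_count = hap0_count if hap == 0 else cfg.site_depth - hap0_count
            sites.append(PhasedSiteRecord(
                chrom=chrom, pos=pos, hap=hap, ref_count=ref_count,
                alt_count=cfg.site_depth - ref_count, sample_id=sample_id))
    return sites


# ------------------------------------------------------- expression etc.

def _simulate_expression(cfg, rng, primary_id, met_id, normal_id):
    genes = immune_panel(cfg.n_immune_genes) + [
        f"EXP{i + 1:03d}"
        for i in range(cfg.n_expression_genes - cfg.n_immune_genes)]
    base = rng.lognormal(mean=4.0, sigma=1.0, size=len(genes))
    is_immune = np.array([g.startswith("IMM") for g in genes])
    means = {
        primary_id: np.where(is_immune, base * 2.0, base),
        met_id: np.where(is_immune, base * 2.0 * cfg.immune_effect, base),
        normal_id: base,
    }
    counts = {sid: rng.poisson(mu) for sid, mu in means.items()}
    return pd.DataFrame(counts, index=genes).astype(float)


def _simulate_methylation(cfg, rng, expression):
    genes = list(expression.index[:cfg.n_methylation_genes])
    logx = np.log2(expression.loc[genes] + 1)
    beta = pd.DataFrame(
        rng.uniform(0.2, 0.8, size=(len(genes), expression.shape[1])),
        index=genes, columns=expression.columns)
    reg = genes[:cfg.n_meth_regulated]
    span = logx.loc[reg].max(axis=1) - logx.loc[reg].min(axis=1)
    span = span.replace(0, 1.0)
    norm = logx.loc[reg].sub(logx.loc[reg].min(axis=1), axis=0).div(span, axis=0)
    noise = rng.normal(0, 0.02, size=norm.shape)
    beta.loc[reg] = np.clip(1.0 - norm.values + noise, 0.0, 1.0)
    return beta


# ------------------------------------------------------------ simulation

def simulate_patient(config: SimConfig, seed: int, patient_id: str = "PT1",
                     signatures: pd.DataFrame | None = None,
                     seeding_mode: str | None = None
                     ) -> tuple[PatientBundle, GroundTruth]:
    """Simulate one paired patient and its ground truth."""
    mode = seeding_mode or config.seeding_mode
    if mode == "mixed":
        raise ConfigError("'mixed' applies to cohorts; pick a mode per patient")
    if mode not in ("monoclonal", "polyclonal"):
        raise ConfigError(f"unknown seeding mode {mode!r}")
    if not 0 < config.purity <= 1:
        raise ConfigError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if signatures is None:
        signatures = synthetic_signatures(config.n_signatures)
    pid = patient_id
    primary_id, met_id, normal_id = f"{pid}_P", f"{pid}_M", f"{pid}_N"
    meta = [
        SampleMeta(primary_id, pid, "primary", "lung", config.purity),
        SampleMeta(met_id, pid, "metastasis", "brain", config.purity),
        SampleMeta(normal_id, pid, "normal", "blood"),
    ]
    gene_model = toy_gene_model()

    cn_by_sample, slot_labels = _simulate_scna(config, rng, primary_id, met_id)
    segments = (_segments_from_cn(cn_by_sample[primary_id], primary_id, config.purity)
                + _segments_from_cn(cn_by_sample[met_id], met_id, config.purity))

    clones = _make_clone_tree(config, mode, rng, primary_id, met_id, signatures)
    mutations, clone_of = _simulate_mutations(
        config, rng, clones, cn_by_sample, gene_model, signatures,
        primary_id, met_id)

    phased_sites: dict[str, list[PhasedSiteRecord]] = {}
    ai_truth: dict[str, list[tuple[str, int, int]]] = {
        primary_id: [], met_id: [], normal_id: []}
    if config.include_ai:
        lo = config.sites_per_chrom // 3
        hi = lo + max(100, config.sites_per_chrom // 2) - 1
        hi = min(hi, config.sites_per_chrom - 1)
        spacing = CHROM_LEN // (config.sites_per_chrom + 1)
        trunk_region = ("1", lo, hi)
        met_region = ("2", lo, hi)
        regions_by_sample = {
            primary_id: [trunk_region],
            met_id: [trunk_region, met_region],
            normal_id: [],
        }
        for sid, regions in regions_by_sample.items():
            phased_sites[sid] = _simulate_sites(config, rng, sid, regions)
            ai_truth[sid] = [(ch, (l + 1) * spacing, (h + 1) * spacing)
                             for ch, l, h in regions]

    expression = methylation = None
    if config.include_expression:
        expression = _simulate_expression(config, rng, primary_id, met_id,
                                          normal_id)
        methylation = _simulate_methylation(config, rng, expression)

    # ground-truth SCNA gene calls
    scna_calls = {}
    for sid in (primary_id, met_id):
        calls = {}
        for row in gene_model.itertuples(index=False):
            slot = _slot_of(row.chrom, row.start)
            cnv = int(cn_by_sample[sid][slot])
            calls[row.gene] = ("gain" if cnv > 2
                               else "loss" if cnv < 2 else "neutral")
        scna_calls[sid] = calls
    n_events = config.scna_trunk + config.scna_primary + config.scna_metastasis
    scna_trunk_fraction = (config.scna_trunk / n_events if n_events else
                           float("nan"))

    total = sum(c.n_mutations for c in clones)
    shared_truth = sum(
        c.n_mutations for c in clones
        if c.ccf_by_sample[primary_id] > 0 and c.ccf_by_sample[met_id] > 0)
    k = signatures.shape[1]
    mixes: dict[str, np.ndarray] = {"shared": clones[0].signature_mix}
    for cat, sid in (("primary_only", primary_id),
                     ("metastasis_only", met_id)):
        members = [c for c in clones[1:]
                   if c.ccf_by_sample[sid] > 0
                   and min(c.ccf_by_sample.values()) == 0]
        if members:
            w = np.array([c.n_mutations for c in members], dtype=float)
            mix = sum(wi * c.signature_mix for wi, c in zip(w, members)) / w.sum()
        else:
            mix = np.full(k, np.nan)
        mixes[cat] = mix

    bundle = PatientBundle(
        patient_id=pid, meta=meta, mutations=mutations, segments=segments,
        phased_sites=phased_sites, expression=expression,
        methylation=methylation)
    truth = GroundTruth(
        seeding_mode=mode, clones=clones, clone_of_mutation=clone_of,
        trunk_fraction=shared_truth / total,
        category_mixes=mixes, scna_calls=scna_calls,
        scna_trunk_fraction=scna_trunk_fraction, ai_regions=ai_truth,
        immune_effect=config.immune_effect)
    return bundle, truth


def cohort_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-patient seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def simulate_cohort(n_patients: int, config: SimConfig, seed: int,
                    outdir=None,
                    signatures: pd.DataFrame | None = None
                    ) -> tuple[list[tuple[PatientBundle, GroundTruth]],
                               pd.DataFrame]:
    """Simulate a cohort; mode 'mixed' alternates monoclonal/polyclonal.

    Returns the per-patient (bundle, truth) list and a manifest frame;
    with ``outdir`` set, writes every patient's files and the manifest.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be >= 1")
    if signatures is None:
        signatures = synthetic_signatures(config.n_signatures)
    seeds = cohort_seeds(seed, n_patients)
    out = []
    rows = []
    for i, patient_seed in enumerate(seeds):
        pid = f"PT{i + 1:03d}"
        if config.seeding_mode == "mixed":
            mode = "monoclonal" if i % 2 == 0 else "polyclonal"
        else:
            mode = config.seeding_mode
        bundle, truth = simulate_patient(
            config, patient_seed, patient_id=pid, signatures=signatures,
            seeding_mode=mode)
        out.append((bundle, truth))
        rows.append({
            "patient_id": pid, "seed": patient_seed, "seeding_mode": mode,
            "n_mutations": sum(c.n_mutations for c in truth.clones),
            "n_clones": len(truth.clones),
            "trunk_fraction": round(truth.trunk_fraction, 6),
        })
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        manifest.to_csv(os.path.join(outdir, "manifest.tsv"), sep="\t",
                        index=False)
        for bundle, _ in out:
            write_bundle(bundle, os.path.join(outdir, bundle.patient_id))
    return out, manifest


def write_bundle(bundle: PatientBundle, outdir) -> None:
    """Write a patient's files in the pipeline's external formats."""
    os.makedirs(outdir, exist_ok=True)
    write_mutations(bundle.mutations, os.path.join(outdir, "mutations.tsv"))
    write_segments(bundle.segments, os.path.join(outdir, "segments.seg"))
    write_sample_meta(bundle.meta, os.path.join(outdir, "samples.tsv"))
    all_sites = [s for sites in bundle.phased_sites.values() for s in sites]
    if all_sites:
        write_phased_sites(all_sites, os.path.join(outdir, "phased_sites.tsv"))
    if bundle.expression is not None:
        write_matrix(bundle.expression, os.path.join(outdir, "expression.tsv"))
    if bundle.methylation is not None:
        write_matrix(bundle.methylation, os.path.join(outdir, "methylation.tsv"))


def config_to_yaml(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"simulate": asdict(config)}, fh)
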