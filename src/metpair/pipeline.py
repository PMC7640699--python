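"""End-to-end orchestration over a paired cohort.

``run_all`` drives every stage per patient — filtering, mutation
partition, CCF clustering and seeding call, genetic distances, signature
refitting, SCNA concordance, allelic imbalance, immune scoring — and
writes one JSON per patient plus a cohort summary TSV. Stage failures
are isolated per patient and surfaced in the report rather than
aborting the run. ``cohort_compare`` applies the paired two-sided
Wilcoxon signed-rank test to primary-vs-metastasis metrics across
patients.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from metpair import (
    allelic_imbalance as ai_mod,
    ccf_clonality,
    expression_immune,
    genetic_distance,
    scna_concordance,
    seeding_inference,
    signature_fit,
    synthetic_cohort,
    variant_filtering,
)

logger = logging.getLogger("metpair")

_PIPELINE_KEYS = {
    "seed", "n_patients", "outdir", "simulate", "min_cluster_size", "k_max",
    "min_shared_ccf", "min_contribution", "min_mutations", "rescue",
    "distance_metrics",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_patients: int = 8
    outdir: str = "metpair_out"
    simulate: synthetic_cohort.SimConfig = field(
        default_factory=synthetic_cohort.SimConfig)
    min_cluster_size: int = 5
    k_max: int = 8
    min_shared_ccf: float = 0.05
    min_contribution: float = 0.06
    min_mutations: int = 50
    rescue: bool = True
    distance_metrics: tuple = ("nei", "meanabs", "jaccard")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _PIPELINE_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = data.pop("simulate", {})
        cfg = cls(**data)
        cfg.simulate = synthetic_cohort.SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distance_metrics"] = list(self.distance_metrics)
        return d


def analyze_patient(bundle, config: PipelineConfig,
                    signatures: pd.DataFrame,
                    seed: int = 0) -> dict:
    """Run every analysis stage for one patient bundle; failures of one
    stage are recorded and do not stop the others."""
    p_id, m_id = bundle.primary_id, bundle.metastasis_id
    purity = {m.sample_id: m.purity for m in bundle.meta if m.role != "normal"}
    result: dict = {"patient_id": bundle.patient_id, "warnings": []}

    def stage(name, fn):
        try:
            result[name] = fn()
        except Exception as exc:  # isolated per stage
            logger.warning("patient %s stage %s failed: %s",
                           bundle.patient_id, name, exc)
            result["warnings"].append(f"{name}: {exc}")
            result[name] = None

    muts_p = bundle.mutations_of(p_id)
    muts_m = bundle.mutations_of(m_id)
    kept_p, _ = variant_filtering.apply_filters(muts_p)
    kept_m, _ = variant_filtering.apply_filters(muts_m)
    result["tmb"] = {
        p_id: variant_filtering.compute_tmb(kept_p, p_id),
        m_id: variant_filtering.compute_tmb(kept_m, m_id),
    }

    def _partition():
        part = seeding_inference.partition_mutations(
            kept_p, kept_m, muts_p, muts_m, rescue=config.rescue)
        return {
            "shared": len(part.shared),
            "primary_only": len(part.primary_only),
            "metastasis_only": len(part.metastasis_only),
            "shared_fraction": part.shared_fraction,
        }
    stage("partition", _partition)

    model = ccf_clonality.CloneModel.from_mutations(
        kept_p + kept_m, purity, bundle.segments)
    fit = model.fit(k_max=config.k_max,
                    min_cluster_size=config.min_cluster_size, seed=seed)

    def _seeding():
        call = seeding_inference.call_seeding_mode(
            fit.clusters, p_id, m_id, min_shared_ccf=config.min_shared_ccf,
            patient_id=bundle.patient_id)
        return {
            "mode": call.mode,
            "n_clusters": fit.n_clusters,
            "founding_cluster": call.founding_cluster_id,
            "shared_clusters": list(call.shared_cluster_ids),
        }
    stage("seeding", _seeding)

    def _distances():
        cols = {s: j for j, s in enumerate(model.sample_ids)}
        x = model.naive_ccf[:, cols[p_id]]
        y = model.naive_ccf[:, cols[m_id]]
        return {m: genetic_distance.METRICS[m](x, y)
                for m in config.distance_metrics}
    stage("distances", _distances)

    def _signatures():
        part = seeding_inference.partition_mutations(
            kept_p, kept_m, muts_p, muts_m, rescue=config.rescue)
        by_key = {}
        for m in muts_p + muts_m:
            by_key.setdefault(m.key, m)
        out = {}
        for cat, keys in (("shared", part.shared),
                          ("primary_only", part.primary_only),
                          ("metastasis_only", part.metastasis_only)):
            cat_muts = [by_key[k] for k in keys if k in by_key]
            catalog = signature_fit.build_catalog(cat_muts, cat)
            if catalog.counts.sum() == 0:
                out[cat] = None
                continue
            res = signature_fit.fit_exposures(
                catalog, signatures, min_contribution=config.min_contribution)
            out[cat] = {"n_mutations": res.n_mutations,
                        "cosine": res.cosine,
                        "weights": res.weights.to_dict()}
        return out
    stage("signatures", _signatures)

    def _scna():
        gene_model = synthetic_cohort.toy_gene_model()
        segs_p = [s for s in bundle.segments if s.sample_id == p_id]
        segs_m = [s for s in bundle.segments if s.sample_id == m_id]
        lp = scna_concordance.assign_gene_log2(segs_p, gene_model)
        lm = scna_concordance.assign_gene_log2(segs_m, gene_model)
        pair = scna_concordance.gene_calls_for_pair(
            lp, lm, purity[p_id], purity[m_id])
        labels, props = scna_concordance.classify_scna_events(pair)
        bp = scna_concordance.scna_burden(pair["primary_call"].values)
        bm = scna_concordance.scna_burden(pair["metastasis_call"].values)
        return {
            "proportions": props,
            "burden": {p_id: {"gain": bp[0], "loss": bp[1]},
                       m_id: {"gain": bm[0], "loss": bm[1]}},
            "shared_fraction": props.get("trunk"),
        }
    stage("scna", _scna)

    def _ai():
        if not bundle.phased_sites:
            return None
        events = {sid: ai_mod.detect_ai(sites)
                  for sid, sites in bundle.phased_sites.items()}
        roles = {m.sample_id: m.role for m in bundle.meta}
        labels = ai_mod.label_segments(events, bundle.phased_sites, roles)
        burdens = {sid: ai_mod.ai_burden(evs) for sid, evs in events.items()}
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab.label] = counts.get(lab.label, 0) + 1
        return {
            "burden": {sid: {"segments": b[0], "bp": b[1]}
                       for sid, b in burdens.items()},
            "segment_labels": counts,
        }
    stage("ai", _ai)

    def _immune():
        if bundle.expression is None:
            return None
        logcpm = expression_immune.normalize_log_cpm(bundle.expression)
        z = expression_immune.zscore_genes(logcpm)
        panel = synthetic_cohort.immune_panel()
        score = expression_immune.immune_score(z, panel)
        return {sid: float(v) for sid, v in score.items()}
    stage("immune", _immune)

    return result


def run_all(config: PipelineConfig) -> pd.DataFrame:
    """Simulate (or load) the cohort, run every stage per patient, write
    per-patient JSONs, a cohort TSV, and echo the config for provenance.
    Returns the cohort summary frame."""
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "config_used.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    signatures = synthetic_cohort.synthetic_signatures(
        config.simulate.n_signatures)
    cohort, manifest = synthetic_cohort.simulate_cohort(
        config.n_patients, config.simulate, config.seed,
        signatures=signatures)
    manifest.to_csv(os.path.join(config.outdir, "manifest.tsv"), sep="\t",
                    index=False)
    seeds = synthetic_cohort.cohort_seeds(config.seed + 1, len(cohort))
    rows = []
    for (bundle, truth), fit_seed in zip(cohort, seeds):
        res = analyze_patient(bundle, config, signatures, seed=fit_seed)
        res["truth"] = {"seeding_mode": truth.seeding_mode,
                        "trunk_fraction": truth.trunk_fraction}
        path = os.path.join(config.outdir, f"{bundle.patient_id}.json")
        with open(path, "w") as fh:
            json.dump(res, fh, indent=2, default=_jsonable)
        p_id, m_id = bundle.primary_id, bundle.metastasis_id
        rows.append({
            "patient_id": bundle.patient_id,
            "true_mode": truth.seeding_mode,
            "called_mode": (res["seeding"] or {}).get("mode"),
            "shared_fraction": (res["partition"] or {}).get("shared_fraction"),
            "true_trunk_fraction": truth.trunk_fraction,
            "nei": (res["distances"] or {}).get("nei"),
            "meanabs": (res["distances"] or {}).get("meanabs"),
            "jaccard": (res["distances"] or {}).get("jaccard"),
            "tmb_primary": res["tmb"][p_id],
            "tmb_metastasis": res["tmb"][m_id],
            "scna_trunk_fraction": (res["scna"] or {}).get("shared_fraction"),
            "immune_primary": (res["immune"] or {}).get(p_id),
            "immune_metastasis": (res["immune"] or {}).get(m_id),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(config.outdir, "cohort_summary.tsv"),
                   sep="\t", index=False)
    return summary


def cohort_compare(summary: pd.DataFrame,
                   metric_pairs: dict[str, tuple[str, str]] | None = None
                   ) -> pd.DataFrame:
    """Paired two-sided Wilcoxon tests of primary vs metastasis metrics.

    ``metric_pairs`` maps a metric name to its (primary column,
    metastasis column) in the cohort summary.
    """
    if metric_pairs is None:
        metric_pairs = {
            "tmb": ("tmb_primary", "tmb_metastasis"),
            "immune_score": ("immune_primary", "immune_metastasis"),
        }
    if len(summary) < 3:
        raise ValueError("need at least 3 patients for a paired comparison")
    rows = []
    for name, (pc, mc) in metric_pairs.items():
        sub = summary[[pc, mc]].dropna()
        a = sub[pc].values.astype(float)
        b = sub[mc].values.astype(float)
        if len(a) < 3:
            raise ValueError(f"metric {name}: fewer than 3 complete pairs")
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
        rows.append({"metric": name, "n": len(a),
                     "mean_primary": a.mean(), "mean_metastasis": b.mean(),
                     "p_value": p})
    return pd.DataFrame(rows).set_index("metric")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
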