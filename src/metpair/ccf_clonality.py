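"""Cancer-cell-fraction estimation and joint clustering of paired samples.

The cancer cell fraction (CCF) of a mutation is the fraction of cancer
cells in a sample that carry it. For a mutation with variant allele
frequency ``vaf`` at a locus with tumor copy number ``cn_t`` and mutation
multiplicity ``m`` in a sample of purity ``rho``::

    ccf = vaf * (rho * cn_t + 2 * (1 - rho)) / (rho * m)    (capped at 1)

Joint clustering across the paired primary/metastasis samples uses a
finite binomial mixture: cluster k has a latent CCF ``phi[k, s]`` per
sample s, and a mutation's alt-read count in sample s is
Binomial(depth, c * phi[k, s]) where c is the per-mutation CCF-to-VAF
scale factor above. The mixture is fitted by EM for K = 1..k_max with
seeded k-means++-style initialization and multiple restarts, and K is
selected by BIC. Clusters smaller than ``min_cluster_size`` (default 5,
the conventional floor for interpretable clones) are dissolved and their
members reassigned to the nearest surviving cluster.

This deterministic EM stage fills the role a Dirichlet-process sampler
plays in larger studies while keeping the same downstream contract:
clusters with per-sample mean CCFs.

Only SNVs enter clustering (indel VAFs are noisier); indels still carry
CCFs for distance and sharing statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metpair.io_formats import CNSegmentRecord, MutationRecord

_EPS = 1e-9

#: depth at which zero alt reads is treated as confident absence (CCF 0)
ABSENT_MIN_DEPTH = 20


def estimate_ccf(vaf: float, purity: float, cn_t: float, multiplicity: int = 1) -> float:
    """CCF from VAF, purity, local tumor copy number and multiplicity.

    Capped at 1.0 (sampling noise can push the raw estimate above it).
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if cn_t < 1:
        raise ValueError("cn_t must be >= 1")
    if not 1 <= multiplicity <= cn_t:
        raise ValueError("multiplicity must be in [1, cn_t]")
    ccf = vaf * (purity * cn_t + 2 * (1 - purity)) / (purity * multiplicity)
    return min(1.0, float(ccf))


def estimate_multiplicity(vaf: float, purity: float, cn_t: float) -> int:
    """Integer mutation multiplicity: the rounded number of mutated copies
    implied by the VAF under a fully clonal assumption, clamped to [1, cn_t]."""
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    raw = vaf * (purity * cn_t + 2 * (1 - purity)) / purity
    return int(np.clip(np.round(raw), 1, max(1, int(cn_t))))


def ccf_scale_factor(purity: np.ndarray, cn_t: np.ndarray, multiplicity: np.ndarray) -> np.ndarray:
    """c such that expected VAF = c * CCF."""
    return purity * multiplicity / (purity * cn_t + 2 * (1 - purity))


@dataclass(frozen=True)
class CloneCluster:
    """A mutation cluster with per-sample mean CCFs."""

    cluster_id: int
    mean_ccf_by_sample: dict[str, float]
    members: tuple
    size: int = 0

    def __post_init__(self):
        if self.size == 0:
            object.__setattr__(self, "size", len(self.members))


@dataclass
class CCFEntry:
    """Per-mutation CCF across the paired samples."""

    key: tuple
    ccf_by_sample: dict[str, float]
    multiplicity: int = 1
    cn_by_sample: dict[str, float] = field(default_factory=dict)


class CloneModel:
    """Joint binomial-mixture model of mutation CCFs across paired samples.

    Parameters
    ----------
    alt, depth : (n_mutations, n_samples) integer arrays
        Alt and total read counts per mutation per sample.
    purity : (n_samples,) array
        Tumor purity per sample, each in (0, 1].
    cn_t : (n_mutations, n_samples) array, optional
        Local tumor copy number (default 2 everywhere).
    multiplicity : (n_mutations,) or (n_mutations, n_samples) array, optional
        Mutated copies (default 1). Per-sample values matter when a gain
        is private to one sample of the pair.
    sample_ids, mutation_keys : labels (defaults generated).
    """

    def __init__(self, alt, depth, purity, cn_t=None, multiplicity=None,
                 sample_ids=None, mutation_keys=None):
        self.alt = np.asarray(alt, dtype=float)
        self.depth = np.asarray(depth, dtype=float)
        if self.alt.shape != self.depth.shape or self.alt.ndim != 2:
            raise ValueError("alt and depth must be (n_mutations, n_samples)")
        if np.any(self.alt > self.depth):
            raise ValueError("alt counts exceed depth")
        n, s = self.alt.shape
        self.purity = np.asarray(purity, dtype=float)
        if self.purity.shape != (s,) or np.any(self.purity <= 0) or np.any(self.purity > 1):
            raise ValueError("purity must be (n_samples,) in (0, 1]")
        self.cn_t = (np.full((n, s), 2.0) if cn_t is None
                     else np.asarray(cn_t, dtype=float))
        if multiplicity is None:
            self.multiplicity = np.ones((n, s))
        else:
            mult = np.asarray(multiplicity, dtype=float)
            self.multiplicity = (np.repeat(mult[:, None], s, axis=1)
                                 if mult.ndim == 1 else mult)
        self.sample_ids = list(sample_ids) if sample_ids is not None else [
            f"S{j}" for j in range(s)]
        self.mutation_keys = (list(mutation_keys) if mutation_keys is not None
                              else list(range(n)))
        # CCF -> VAF scale per mutation per sample
        self.scale = ccf_scale_factor(
            self.purity[None, :], self.cn_t, self.multiplicity)
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = np.where(self.depth > 0, self.alt / np.maximum(self.depth, 1), 0.0)
        self.naive_ccf = np.clip(vaf / self.scale, 0.0, 1.0)

    @classmethod
    def from_mutations(cls, mutations: list[MutationRecord],
                       purity_by_sample: dict[str, float],
                       segments: list[CNSegmentRecord] | None = None,
                       snv_only: bool = True) -> "CloneModel":
        """Build a model from per-sample mutation records.

        The mutation universe is the union of keys across samples; a key
        missing from a sample gets 0 alt reads at depth
        :data:`ABSENT_MIN_DEPTH` (confident absence). Local copy number is
        looked up from the containing segment (the observed ratio is
        de-mixed with the sample purity and rounded); default 2 when
        uncovered. Multiplicity is estimated per sample from that sample's
        own VAF — it can legitimately differ between samples when a gain
        is private to one of them.
        """
        if snv_only:
            mutations = [m for m in mutations if m.is_snv]
        samples = sorted(purity_by_sample)
        keys = sorted({m.key for m in mutations})
        idx = {k: i for i, k in enumerate(keys)}
        sidx = {s: j for j, s in enumerate(samples)}
        n = len(keys)
        alt = np.zeros((n, len(samples)))
        depth = np.full((n, len(samples)), float(ABSENT_MIN_DEPTH))
        for m in mutations:
            if m.sample_id not in sidx:
                continue
            i, j = idx[m.key], sidx[m.sample_id]
            alt[i, j] = m.t_alt
            depth[i, j] = m.t_depth
        cn = np.full((n, len(samples)), 2.0)
        if segments:
            cn_lookup = _segment_cn_lookup(segments, purity_by_sample)
            for k, i in idx.items():
                for s, j in sidx.items():
                    val = cn_lookup(s, k[0], k[1])
                    if val is not None:
                        cn[i, j] = val
        purity = np.array([purity_by_sample[s] for s in samples])
        with np.errstate(invalid="ignore"):
            vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        mult = np.ones((n, len(samples)))
        for i in range(n):
            for j in range(len(samples)):
                mult[i, j] = estimate_multiplicity(vaf[i, j], purity[j],
                                                   cn[i, j])
        return cls(alt, depth, purity, cn_t=cn, multiplicity=mult,
                   sample_ids=samples, mutation_keys=keys)

    # ---------------------------------------------------------------- EM

    def _loglik_matrix(self, phi: np.ndarray) -> np.ndarray:
        """(n, K) per-mutation log-likelihood under each cluster CCF."""
        p = np.clip(self.scale[:, :, None] * phi.T[None, :, :], _EPS, 1 - _EPS)
        a = self.alt[:, :, None]
        d = self.depth[:, :, None]
        return np.sum(a * np.log(p) + (d - a) * np.log1p(-p), axis=1)

    def _em(self, phi0: np.ndarray, max_iter: int = 200, tol: float = 1e-7):
        n = self.alt.shape[0]
        k = phi0.shape[0]
        phi = phi0.copy()
        pi = np.full(k, 1.0 / k)
        prev = -np.inf
        for _ in range(max_iter):
            ll = self._loglik_matrix(phi) + np.log(np.maximum(pi, _EPS))[None, :]
            m = ll.max(axis=1, keepdims=True)
            resp = np.exp(ll - m)
            norm = resp.sum(axis=1, keepdims=True)
            resp /= norm
            total = float(np.sum(m[:, 0] + np.log(norm[:, 0])))
            pi = resp.mean(axis=0)
            # pooled-count CCF update: exact MLE when scale is constant
            num = resp.T @ self.alt                        # (K, S)
            den = resp.T @ (self.depth * self.scale)       # (K, S)
            phi = np.clip(num / np.maximum(den, _EPS), 0.0, 1.0)
            if abs(total - prev) < tol * max(1.0, abs(total)):
                prev = total
                break
            prev = total
        return phi, pi, resp, prev

    def fit(self, k_max: int = 8, min_cluster_size: int = 5,
            n_restarts: int = 10, seed: int = 0) -> "CloneModelResults":
        """Fit the mixture for K = 1..k_max, select K by BIC."""
        n, s = self.alt.shape
        rng = np.random.default_rng(seed)
        if n < min_cluster_size:
            warnings.warn(
                f"only {n} mutations (< {min_cluster_size}); "
                "falling back to a single cluster")
            phi, pi, resp, ll = self._em(self.naive_ccf.mean(axis=0, keepdims=True))
            return self._package(phi, resp, ll, {1: self._bic(ll, 1)},
                                 min_cluster_size)
        best = {}
        bics = {}
        for k in range(1, min(k_max, n) + 1):
            best_ll, best_fit = -np.inf, None
            for _ in range(n_restarts):
                phi0 = self._init_phi(k, rng)
                phi, pi, resp, ll = self._em(phi0)
                if ll > best_ll:
                    best_ll, best_fit = ll, (phi, pi, resp, ll)
            bics[k] = self._bic(best_ll, k)
            best[k] = best_fit
        k_star = min(bics, key=lambda k: (bics[k], k))
        phi, pi, resp, ll = best[k_star]
        return self._package(phi, resp, ll, bics, min_cluster_size)

    def _bic(self, ll: float, k: int) -> float:
        n, s = self.alt.shape
        n_params = k * s + (k - 1)
        return -2 * ll + n_params * np.log(max(n, 2))

    def _init_phi(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """k-means++-style seeding on the naive per-mutation CCF vectors."""
        x = self.naive_ccf
        n = x.shape[0]
        centers = [x[rng.integers(n)]]
        for _ in range(1, k):
            d2 = np.min(
                [np.sum((x - c) ** 2, axis=1) for c in centers], axis=0)
            tot = d2.sum()
            if tot <= 0:
                centers.append(x[rng.integers(n)])
                continue
            centers.append(x[rng.choice(n, p=d2 / tot)])
        phi = np.clip(np.array(centers), 0.01, 1.0)
        return phi

    def _package(self, phi, resp, ll, bics, min_cluster_size) -> "CloneModelResults":
        assign = np.argmax(resp, axis=1)
        # dissolve undersized clusters, reassign members to nearest survivor
        sizes = np.bincount(assign, minlength=phi.shape[0])
        surviving = [k for k in range(phi.shape[0]) if sizes[k] >= min_cluster_size]
        if not surviving:
            surviving = [int(np.argmax(sizes))]
        phi_s = phi[surviving]
        d2 = np.sum((self.naive_ccf[:, None, :] - phi_s[None, :, :]) ** 2, axis=2)
        new_assign = np.empty_like(assign)
        surv_index = {k: i for i, k in enumerate(surviving)}
        for i, k in enumerate(assign):
            new_assign[i] = surv_index[k] if k in surv_index else int(np.argmin(d2[i]))
        # re-estimate cluster CCFs from final hard assignment (pooled counts)
        means = np.zeros_like(phi_s)
        for ci in range(len(surviving)):
            mask = new_assign == ci
            num = self.alt[mask].sum(axis=0)
            den = (self.depth[mask] * self.scale[mask]).sum(axis=0)
            means[ci] = np.clip(num / np.maximum(den, _EPS), 0.0, 1.0)
        clusters = []
        for ci in range(len(surviving)):
            members = tuple(self.mutation_keys[i]
                            for i in np.flatnonzero(new_assign == ci))
            clusters.append(CloneCluster(
                cluster_id=ci,
                mean_ccf_by_sample={s: float(means[ci, j])
                                    for j, s in enumerate(self.sample_ids)},
                members=members,
            ))
        return CloneModelResults(self, clusters, new_assign, float(ll), dict(bics))


class CloneModelResults:
    """Fitted clone clusters with per-sample mean CCFs.

    Attributes
    ----------
    clusters : list of CloneCluster
    assignments : (n_mutations,) cluster index per mutation
    loglik : best log-likelihood at the selected K
    bic_by_k : BIC for each candidate K
    """

    def __init__(self, model: CloneModel, clusters, assignments, loglik, bic_by_k):
        self.model = model
        self.clusters = clusters
        self.assignments = assignments
        self.loglik = loglik
        self.bic_by_k = bic_by_k

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def ccf_table(self) -> pd.DataFrame:
        """Per-mutation naive CCFs plus cluster assignment."""
        df = pd.DataFrame(self.model.naive_ccf, columns=self.model.sample_ids)
        df.insert(0, "mutation", [str(k) for k in self.model.mutation_keys])
        df["cluster"] = self.assignments
        return df

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            row = {"cluster_id": c.cluster_id, "size": c.size}
            row.update({f"ccf_{s}": v for s, v in c.mean_ccf_by_sample.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def clonal_cluster(self, sample_id: str) -> int:
        return designate_clonal(self.clusters, sample_id)

    def summary(self) -> str:
        lines = [
            "Clone model (binomial mixture, EM + BIC)",
            f"  mutations: {self.model.alt.shape[0]}   "
            f"samples: {', '.join(self.model.sample_ids)}",
            f"  selected K: {self.n_clusters}   log-likelihood: {self.loglik:.2f}",
            "  BIC by K: " + "  ".join(
                f"{k}:{v:.1f}" for k, v in sorted(self.bic_by_k.items())),
            "",
            self.cluster_table().to_string(index=False),
        ]
        return "\n".join(lines)


def cluster_ccf(alt, depth, purity, cn_t=None, multiplicity=None,
                sample_ids=None, mutation_keys=None,
                min_cluster_size: int = 5, k_max: int = 8,
                seed: int = 0) -> list[CloneCluster]:
    """Functional wrapper: fit :class:`CloneModel` and return the clusters."""
    model = CloneModel(alt, depth, purity, cn_t=cn_t, multiplicity=multiplicity,
                       sample_ids=sample_ids, mutation_keys=mutation_keys)
    return model.fit(k_max=k_max, min_cluster_size=min_cluster_size,
                     seed=seed).clusters


def designate_clonal(clusters: list[CloneCluster], sample_id: str) -> int:
    """Id of the clonal cluster in a sample: maximal mean CCF, ties broken
    by larger size then lower cluster id."""
    if not clusters:
        raise ValueError("no clusters")
    return min(
        clusters,
        key=lambda c: (-c.mean_ccf_by_sample[sample_id], -c.size, c.cluster_id),
    ).cluster_id


def _segment_cn_lookup(segments: list[CNSegmentRecord],
                       purity_by_sample: dict[str, float]):
    """Containing-segment total copy number per (sample, chrom, pos).

    The observed ratio r = 2**log2 is purity-mixed: r = rho*CN/2 + (1-rho),
    so CN = 2*(r - (1-rho))/rho, rounded to the nearest integer >= 1.
    """
    by_sample: dict[str, dict[str, list[CNSegmentRecord]]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, {}).setdefault(seg.chrom, []).append(seg)
    for chroms in by_sample.values():
        for segs in chroms.values():
            segs.sort(key=lambda s: s.start)

    def lookup(sample_id, chrom, pos):
        segs = by_sample.get(sample_id, {}).get(chrom, [])
        for seg in segs:
            if seg.start <= pos <= seg.end:
                rho = purity_by_sample.get(sample_id, 1.0)
                r = 2.0 ** seg.log2_ratio
                cn = 2.0 * (r - (1 - rho)) / rho
                return max(1.0, float(np.round(cn)))
        return None

    return lookup
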