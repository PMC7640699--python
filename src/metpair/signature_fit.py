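"""96-channel mutation catalogs and constrained signature refitting.

Single-base substitutions are encoded in the standard 96-channel,
pyrimidine-centered trinucleotide scheme (6 substitution classes
C>A..T>G x 16 flanking contexts); purine-centered records are
reverse-complemented. Exposures of a known signature matrix (e.g. the 30
COSMIC v2 signatures, supplied by the user as a 96 x K column-stochastic
matrix) are refitted per catalog by non-negative least squares, followed
by iterative zeroing of weights below a minimum-contribution floor
(default 0.06, the convention of established refitting tools) and a
final renormalization to sum 1.

Category-level comparisons (shared vs primary-only vs metastasis-only
mutation sets) use a paired two-sided Wilcoxon signed-rank test across
patients, restricted to patients with more than ``min_mutations``
(default 50) mutations in every category — small catalogs give unstable
exposures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from metpair.io_formats import MutationRecord

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: fixed channel order: substitution-major, then 5' base, then 3' base
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

CATEGORIES = ("shared", "primary_only", "metastasis_only",
              "all_primary", "all_metastasis")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(ref: str, alt: str, context: str) -> str | None:
    """Map a substitution with trinucleotide context to its 96-channel name,
    standardizing purine-centered records to the pyrimidine strand.
    Returns None for non-SNVs or malformed contexts."""
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        return None
    if context[1] != ref:
        return None
    if ref in "AG":  # purine-centered: complement to the pyrimidine strand
        context = revcomp(context)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    name = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return name if name in _CHANNEL_INDEX else None


@dataclass
class MutationCatalog:
    """Counts over the 96 substitution channels for one mutation category."""

    counts: np.ndarray
    category: str
    n_mutations: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS_96), name=self.category)


def build_catalog(mutations: list[MutationRecord], category: str) -> MutationCatalog:
    """Count SNVs with trinucleotide contexts into a 96-channel catalog.

    Non-SNVs and records without a usable context are excluded; counts
    sum to the number of included mutations.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    counts = np.zeros(96, dtype=float)
    n = 0
    for m in mutations:
        ch = channel_of(m.ref, m.alt, m.context)
        if ch is None:
            continue
        counts[_CHANNEL_INDEX[ch]] += 1
        n += 1
    return MutationCatalog(counts=counts, category=category, n_mutations=n)


def catalog_from_channels(channels: list[str], category: str = "shared") -> MutationCatalog:
    counts = np.zeros(96, dtype=float)
    for ch in channels:
        counts[_CHANNEL_INDEX[ch]] += 1
    return MutationCatalog(counts=counts, category=category,
                           n_mutations=len(channels))


def _validate_signatures(signatures: pd.DataFrame) -> pd.DataFrame:
    if signatures.shape[0] != 96:
        raise ValueError("signature matrix must have 96 rows")
    if np.any(signatures.values < 0):
        raise ValueError("signatures must be non-negative")
    sums = signatures.values.sum(axis=0)
    if np.any(np.abs(sums - 1) > 1e-6):
        raise ValueError("signature columns must sum to 1 (within 1e-6)")
    return signatures


class SignatureRefit:
    """Model object: refit known signatures to one mutation catalog."""

    def __init__(self, catalog: MutationCatalog, signatures: pd.DataFrame):
        self.catalog = catalog
        self.signatures = _validate_signatures(signatures)
        if catalog.counts.sum() <= 0:
            raise ValueError("cannot fit an all-zero catalog")

    def fit(self, min_contribution: float = 0.06) -> "SignatureRefitResults":
        v = self.catalog.counts / self.catalog.counts.sum()
        s = self.signatures.values
        names = list(self.signatures.columns)
        active = np.ones(len(names), dtype=bool)
        while True:
            w = np.zeros(len(names))
            w_active, _ = optimize.nnls(s[:, active], v)
            w[active] = w_active
            total = w.sum()
            norm = w / total if total > 0 else w
            drop = active & (norm < min_contribution) & (norm > 0)
            # also deactivate exact zeros so the active set shrinks monotonically
            drop |= active & (w == 0)
            if not drop.any() or not (active & ~drop).any():
                break
            active = active & ~drop
        norm = np.where(norm >= min_contribution, norm, 0.0)
        total = norm.sum()
        if total > 0:
            norm = norm / total
        recon = s @ (norm * v.sum())
        cos = _cosine(v, recon)
        return SignatureRefitResults(
            model=self,
            weights=pd.Series(norm, index=names),
            cosine=cos,
            min_contribution=min_contribution,
        )


class SignatureRefitResults:
    """Refitted exposures: non-negative weights summing to 1."""

    def __init__(self, model, weights: pd.Series, cosine: float,
                 min_contribution: float):
        self.model = model
        self.weights = weights
        self.cosine = cosine
        self.min_contribution = min_contribution

    @property
    def n_mutations(self) -> int:
        return self.model.catalog.n_mutations

    def summary(self) -> str:
        active = self.weights[self.weights > 0].sort_values(ascending=False)
        lines = [
            f"Signature refit ({self.model.catalog.category}, "
            f"n={self.n_mutations} mutations)",
            f"  reconstruction cosine similarity: {self.cosine:.4f}",
            f"  minimum contribution: {self.min_contribution:.2f}",
            "",
        ]
        lines += [f"  {name:>12s}  {w:.3f}" for name, w in active.items()]
        return "\n".join(lines)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def fit_exposures(catalog: MutationCatalog, signatures: pd.DataFrame,
                  min_contribution: float = 0.06) -> SignatureRefitResults:
    """Functional wrapper over :class:`SignatureRefit`."""
    return SignatureRefit(catalog, signatures).fit(min_contribution=min_contribution)


def compare_category_exposures(
    per_patient: dict[str, dict[str, SignatureRefitResults]],
    min_mutations: int = 50,
    signature: str | None = None,
) -> pd.DataFrame:
    """Paired comparison of signature contributions across mutation
    categories.

    Patients qualify only if their shared, primary_only and
    metastasis_only catalogs each contain more than ``min_mutations``
    mutations (strictly). For each signature (or the single requested
    one), returns mean contributions per category and two-sided paired
    Wilcoxon signed-rank p-values for shared vs primary-only and shared
    vs metastasis-only.
    """
    needed = ("shared", "primary_only", "metastasis_only")
    eligible = {
        pid: cats for pid, cats in per_patient.items()
        if all(c in cats and cats[c].n_mutations > min_mutations for c in needed)
    }
    if len(eligible) < 3:
        raise ValueError(
            f"only {len(eligible)} patients with > {min_mutations} mutations "
            "in every category; need at least 3")
    any_res = next(iter(eligible.values()))["shared"]
    sig_names = [signature] if signature else list(any_res.weights.index)
    rows = []
    for sig in sig_names:
        w = {c: np.array([eligible[p][c].weights[sig] for p in sorted(eligible)])
             for c in needed}
        rows.append({
            "signature": sig,
            "n_patients": len(eligible),
            "mean_shared": w["shared"].mean(),
            "mean_primary_only": w["primary_only"].mean(),
            "mean_metastasis_only": w["metastasis_only"].mean(),
            "p_shared_vs_primary": _paired_wilcoxon(w["shared"], w["primary_only"]),
            "p_shared_vs_metastasis": _paired_wilcoxon(w["shared"],
                                                       w["metastasis_only"]),
        })
    return pd.DataFrame(rows).set_index("signature")


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    if np.allclose(diff, 0):
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
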