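"""Somatic-mutation filtering, canonical cancer-gene annotation, and TMB.

The filter policy encodes the standard post-calling criteria for paired
tumor/normal exome data: minimum sequencing depth of 50 in tumor and 30
in normal, tumor VAF at least 5% for SNVs and 10% for indels, normal VAF
below 1%, and removal of variants common in population databases
(population allele frequency above 1%). Boundary comparisons follow the
printed inequality symbols exactly (>= for the keep-side thresholds,
strict < for normal VAF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from metpair.io_formats import MutationRecord

# Order matters: each removed record is tagged with the FIRST failing rule.
RULE_ORDER = (
    "min_t_depth", "min_n_depth", "min_vaf_snv", "min_vaf_indel",
    "max_n_vaf", "max_pop_af",
)


@dataclass(frozen=True)
class FilterPolicy:
    min_t_depth: int = 50
    min_n_depth: int = 30
    min_vaf_snv: float = 0.05
    min_vaf_indel: float = 0.10
    max_n_vaf: float = 0.01
    max_pop_af: float = 0.01

    def failing_rule(self, rec: MutationRecord) -> str | None:
        """Name of the first rule the record fails, or None if kept."""
        if rec.t_depth < self.min_t_depth:
            return "min_t_depth"
        if rec.n_depth < self.min_n_depth:
            return "min_n_depth"
        min_vaf = self.min_vaf_snv if rec.is_snv else self.min_vaf_indel
        if rec.vaf < min_vaf:
            return "min_vaf_snv" if rec.is_snv else "min_vaf_indel"
        if not rec.n_vaf < self.max_n_vaf:
            return "max_n_vaf"
        if rec.pop_af > self.max_pop_af:
            return "max_pop_af"
        return None


@dataclass(frozen=True)
class CancerGeneResource:
    """User-supplied cancer-gene catalog for canonical-mutation calls."""

    oncogenes: frozenset[str] = field(default_factory=frozenset)
    tumor_suppressors: frozenset[str] = field(default_factory=frozenset)
    known_aa_changes: frozenset[tuple[str, str]] = field(default_factory=frozenset)


DISRUPTING_EFFECTS = frozenset({"stop-gain", "splicing", "frameshift-indel"})


def apply_filters(
    mutations: list[MutationRecord],
    policy: FilterPolicy | None = None,
) -> tuple[list[MutationRecord], list[tuple[MutationRecord, str]]]:
    """Partition mutations into kept and (removed, reason) per the policy.

    Idempotent: re-filtering the kept set removes nothing. Every input
    record lands in exactly one of the two outputs.
    """
    policy = policy or FilterPolicy()
    kept: list[MutationRecord] = []
    removed: list[tuple[MutationRecord, str]] = []
    for rec in mutations:
        reason = policy.failing_rule(rec)
        if reason is None:
            kept.append(rec)
        else:
            removed.append((rec, reason))
    return kept, removed


def classify_canonical(
    mutation: MutationRecord, resource: CancerGeneResource | None
) -> str:
    """Classify a mutation as ``canonical`` or ``not_canonical``.

    Canonical means either a previously reported amino-acid change in a
    cancer gene (matched on (gene, effect-string) against the supplied
    catalog) or a disrupting mutation (stop-gain, splicing, frameshift
    indel) in a tumor suppressor.
    """
    if resource is None:
        raise ValueError("a CancerGeneResource is required")
    if not mutation.gene:
        raise ValueError("mutation lacks a gene annotation")
    gene = mutation.gene
    in_catalog = gene in resource.oncogenes or gene in resource.tumor_suppressors
    if in_catalog and (gene, mutation.effect) in resource.known_aa_changes:
        return "canonical"
    if mutation.effect in DISRUPTING_EFFECTS and gene in resource.tumor_suppressors:
        return "canonical"
    return "not_canonical"


def compute_tmb(kept_mutations: list[MutationRecord], sample_id: str) -> int:
    """Tumor mutation burden: count of distinct filtered somatic mutations
    in a sample (deduplicated by chrom, pos, ref, alt)."""
    keys = {
        m.key for m in kept_mutations if m.sample_id == sample_id
    }
    return len(keys)
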