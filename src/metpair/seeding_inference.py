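"""Monoclonal vs polyclonal seeding calls, pigeonhole checks, and small
binary parsimony trees.

A metastasis seeded by a single clone shares only the founding (clonal)
cluster with its primary; any additional shared subclone implies
polyclonal seeding. Sharing of a cluster is decided on its mean CCF
exceeding a noise floor in *both* samples. The pigeonhole principle
constrains subclonal architecture: within one sample, sibling clones'
CCFs cannot sum beyond their parent's CCF — a violation forces nesting.

Phylogenies are built from the binary presence matrix (mutation = 1,
wild type = 0, matched normal as the all-zero outgroup) by exhaustive
search over unrooted topologies, scored with Fitch parsimony; branch
lengths are the number of mutations assigned to each branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from metpair.io_formats import MutationRecord


@dataclass(frozen=True)
class MutationPartition:
    """Shared / primary-only / metastasis-only mutation key sets."""

    shared: frozenset
    primary_only: frozenset
    metastasis_only: frozenset

    @property
    def union(self) -> frozenset:
        return self.shared | self.primary_only | self.metastasis_only

    @property
    def shared_fraction(self) -> float:
        u = len(self.union)
        return len(self.shared) / u if u else float("nan")


@dataclass(frozen=True)
class SeedingCall:
    patient_id: str
    mode: str  # monoclonal | polyclonal
    shared_cluster_ids: tuple
    private_cluster_ids_by_sample: dict
    founding_cluster_id: int


def partition_mutations(
    kept_primary: list[MutationRecord],
    kept_metastasis: list[MutationRecord],
    all_primary: list[MutationRecord] | None = None,
    all_metastasis: list[MutationRecord] | None = None,
    rescue: bool = True,
    rescue_min_alt: int = 2,
) -> MutationPartition:
    """Partition a pair's kept mutations into shared / primary-only /
    metastasis-only.

    A mutation kept in one sample counts as present in the other if it was
    kept there too, or — with the rescue rule on — if the other sample's
    unfiltered record shows at least ``rescue_min_alt`` alt reads. The
    rescue rule avoids inflating private calls when a true shared mutation
    narrowly fails a filter in one sample.
    """
    kp = {m.key for m in kept_primary}
    km = {m.key for m in kept_metastasis}
    alt_p = {m.key: m.t_alt for m in (all_primary or [])}
    alt_m = {m.key: m.t_alt for m in (all_metastasis or [])}

    def present_in_m(key):
        return key in km or (rescue and alt_m.get(key, 0) >= rescue_min_alt)

    def present_in_p(key):
        return key in kp or (rescue and alt_p.get(key, 0) >= rescue_min_alt)

    shared = {k for k in kp if present_in_m(k)} | {k for k in km if present_in_p(k)}
    return MutationPartition(
        shared=frozenset(shared),
        primary_only=frozenset(kp - shared),
        metastasis_only=frozenset(km - shared),
    )


def can_be_siblings(ccf_a: float, ccf_b: float, ccf_parent: float,
                    tolerance: float = 0.05) -> bool:
    """Pigeonhole test: two disjoint sibling clones fit under a parent iff
    their CCFs sum to at most the parent CCF (plus estimation tolerance)."""
    return ccf_a + ccf_b <= ccf_parent + tolerance


def check_pigeonhole(clusters, sample_id: str, tolerance: float = 0.05) -> list[tuple]:
    """All cluster pairs whose CCFs in a sample cannot be siblings under
    the clonal cluster — each violation implies the pair must be nested.

    Returns (cluster_id_a, cluster_id_b, ccf_a + ccf_b, parent_ccf) tuples.
    """
    from metpair.ccf_clonality import designate_clonal

    if not clusters:
        return []
    clonal = designate_clonal(clusters, sample_id)
    parent_ccf = next(c for c in clusters if c.cluster_id == clonal
                      ).mean_ccf_by_sample[sample_id]
    subs = [c for c in clusters if c.cluster_id != clonal]
    violations = []
    for i, a in enumerate(subs):
        for b in subs[i + 1:]:
            ca = a.mean_ccf_by_sample[sample_id]
            cb = b.mean_ccf_by_sample[sample_id]
            if not can_be_siblings(ca, cb, parent_ccf, tolerance):
                violations.append((a.cluster_id, b.cluster_id, ca + cb, parent_ccf))
    return violations


def call_seeding_mode(clusters, primary_id: str | None = None,
                      metastasis_id: str | None = None,
                      min_shared_ccf: float = 0.05,
                      patient_id: str = "") -> SeedingCall:
    """Classify a primary/metastasis pair as monoclonal or polyclonal.

    A cluster is shared iff its mean CCF is at least ``min_shared_ccf`` in
    both samples; the call is monoclonal iff the only shared cluster is
    the founding cluster (the one clonal in both samples).
    """
    if not clusters:
        raise ValueError("no clusters")
    sample_ids = sorted(clusters[0].mean_ccf_by_sample)
    if primary_id is None or metastasis_id is None:
        if len(sample_ids) != 2:
            raise ValueError("specify primary_id and metastasis_id")
        primary_id, metastasis_id = sample_ids
    shared = [c for c in clusters
              if c.mean_ccf_by_sample[primary_id] >= min_shared_ccf
              and c.mean_ccf_by_sample[metastasis_id] >= min_shared_ccf]
    if not shared:
        raise ValueError(
            "no common ancestry: no cluster shared between the paired "
            "samples, violating the paired-tumor assumption")
    founding = min(
        shared,
        key=lambda c: (-(c.mean_ccf_by_sample[primary_id]
                         + c.mean_ccf_by_sample[metastasis_id]),
                       -c.size, c.cluster_id))
    mode = "monoclonal" if len(shared) == 1 else "polyclonal"
    private = {
        primary_id: tuple(
            c.cluster_id for c in clusters
            if c.mean_ccf_by_sample[primary_id] >= min_shared_ccf
            and c.mean_ccf_by_sample[metastasis_id] < min_shared_ccf),
        metastasis_id: tuple(
            c.cluster_id for c in clusters
            if c.mean_ccf_by_sample[metastasis_id] >= min_shared_ccf
            and c.mean_ccf_by_sample[primary_id] < min_shared_ccf),
    }
    return SeedingCall(
        patient_id=patient_id,
        mode=mode,
        shared_cluster_ids=tuple(sorted(c.cluster_id for c in shared)),
        private_cluster_ids_by_sample=private,
        founding_cluster_id=founding.cluster_id,
    )


# --------------------------------------------------------------- parsimony

@dataclass
class ParsimonyTree:
    """Best-scoring binary parsimony tree over samples."""

    newick: str
    score: int
    branch_lengths: dict = field(default_factory=dict)


def _enumerate_rooted(leaves: list[int]):
    """All rooted binary leaf-labeled tree shapes over ``leaves``
    (nested-tuple representation); (2k-3)!! of them for k leaves."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in _enumerate_rooted(rest):
        yield from _insert_leaf(sub, first)


def _insert_leaf(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insert_leaf(left, leaf):
            yield (t, right)
        for t in _insert_leaf(right, leaf):
            yield (left, t)


def _fitch_score(tree, outgroup: int, masks: np.ndarray) -> int:
    """Fitch parsimony score of the unrooted tree formed by joining
    ``tree`` with ``outgroup``; ``masks[i]`` is the per-column state
    bitmask of taxon i (1 for state 0, 2 for state 1)."""
    score = np.zeros(masks.shape[1], dtype=np.int64)

    def down(node):
        if not isinstance(node, tuple):
            return masks[node]
        l = down(node[0])
        r = down(node[1])
        inter = l & r
        union = l | r
        empty = inter == 0
        score[empty] += 1
        return np.where(empty, union, inter)

    root_set = down((tree, outgroup))
    return int(score.sum())


def build_parsimony_tree(presence: np.ndarray,
                         sample_ids: list[str],
                         outgroup: str | None = None) -> ParsimonyTree:
    """Exhaustive maximum-parsimony search on a binary presence matrix.

    Parameters
    ----------
    presence : (n_samples, n_mutations) 0/1 matrix
    sample_ids : row labels
    outgroup : sample to root the reported tree at (default: an all-zero
        row if present, else the first sample). The score is over unrooted
        topologies and does not depend on the choice.

    Raises for more than 8 samples (the search is exhaustive; subsample).
    """
    presence = np.asarray(presence, dtype=np.int8)
    if presence.ndim != 2 or presence.shape[0] != len(sample_ids):
        raise ValueError("presence must be (n_samples, n_mutations)")
    if not np.isin(presence, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    n = len(sample_ids)
    if n > 8:
        raise ValueError(
            "exhaustive topology search supports at most 8 samples; "
            "subsample the matrix")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if outgroup is None:
        zeros = [s for s, row in zip(sample_ids, presence) if not row.any()]
        outgroup = zeros[0] if zeros else sample_ids[0]
    og = sample_ids.index(outgroup)
    others = [i for i in range(n) if i != og]
    masks = (1 << presence).astype(np.int8)  # state 0 -> 1, state 1 -> 2

    if len(others) == 1:
        best_tree, best_score = others[0], int(
            (presence[others[0]] != presence[og]).sum())
    else:
        best_tree, best_score = None, None
        for tree in _enumerate_rooted(others):
            s = _fitch_score(tree, og, masks)
            if best_score is None or s < best_score:
                best_tree, best_score = tree, s
    newick, lengths = _resolve_branches(best_tree, og, presence, sample_ids)
    return ParsimonyTree(newick=newick, score=best_score, branch_lengths=lengths)


def _resolve_branches(tree, og, presence, sample_ids):
    """Assign mutations to branches on the tree rooted at the outgroup.

    Bottom-up Fitch state sets, then a top-down pass preferring the parent
    state (ties at the root resolved to the outgroup's state); the length
    of a branch is the number of columns changing state across it.
    """
    counter = [0]
    nodes = {}

    def build(node):
        nid = counter[0]
        counter[0] += 1
        if not isinstance(node, tuple):
            nodes[nid] = {"leaf": node, "children": []}
            nodes[nid]["set"] = (1 << presence[node]).astype(np.int8)
        else:
            left = build(node[0])
            right = build(node[1])
            l, r = nodes[left]["set"], nodes[right]["set"]
            inter = l & r
            nodes[nid] = {"leaf": None, "children": [left, right]}
            nodes[nid]["set"] = np.where(inter == 0, l | r, inter)
        return nid

    root = build((tree, og))
    root_state = np.where(
        nodes[root]["set"] & (1 << presence[og]),
        presence[og],
        (nodes[root]["set"] == 2).astype(np.int8))
    lengths = {}

    def down(nid, parent_state, label):
        node = nodes[nid]
        in_set = (node["set"] >> parent_state) & 1
        state = np.where(in_set == 1, parent_state,
                         (node["set"] == 2).astype(np.int8))
        lengths[label] = int((state != parent_state).sum())
        if node["leaf"] is not None:
            return f"{sample_ids[node['leaf']]}:{lengths[label]}"
        parts = [down(c, state, f"{label}.{i}")
                 for i, c in enumerate(node["children"])]
        return f"({','.join(parts)}):{lengths[label]}"

    children = nodes[root]["children"]
    if children:
        parts = [down(c, root_state, f"n{i}") for i, c in enumerate(children)]
        newick = f"({','.join(parts)});"
    else:
        newick = f"{sample_ids[nodes[root]['leaf']]};"
    return newick, lengths
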