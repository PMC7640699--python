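"""Property-based benchmark evaluations of the pipeline on synthetic data.

Each function regenerates its inputs from scratch at the study
conditions the package documents (200x depth, purity 0.6, subclone CCFs
at least 0.2, etc.), runs the relevant stages, and measures recovery:
CCF estimation error and model-order accuracy, seeding-mode accuracy,
signature-refit fidelity, the calibration of the allelic-imbalance test,
SCNA purity-adjustment exactness, filter-rule correctness, and
end-to-end shared-fraction recovery. They power both the acceptance
script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from metpair import (
    ccf_clonality,
    pipeline,
    scna_concordance,
    seeding_inference,
    signature_fit,
    synthetic_cohort,
    variant_filtering,
)
from metpair.allelic_imbalance import binomial_sharing_test
from metpair.genetic_distance import (
    jaccard_distance,
    mean_abs_ccf_distance,
    nei_distance,
)
from metpair.io_formats import MutationRecord


def distance_examples() -> dict[str, float]:
    """The three distances on the worked two-mutation example
    x = (1.0, 0.5), y = (1.0, 0.0)."""
    x, y = [1.0, 0.5], [1.0, 0.0]
    return {
        "nei": nei_distance(x, y),
        "meanabs": mean_abs_ccf_distance(x, y),
        "jaccard": jaccard_distance(x, y),
    }


def _fit_bundle(bundle, seed):
    purity = {m.sample_id: m.purity for m in bundle.meta
              if m.role != "normal"}
    kept_p, _ = variant_filtering.apply_filters(
        bundle.mutations_of(bundle.primary_id))
    kept_m, _ = variant_filtering.apply_filters(
        bundle.mutations_of(bundle.metastasis_id))
    model = ccf_clonality.CloneModel.from_mutations(
        kept_p + kept_m, purity, bundle.segments)
    return model, model.fit(seed=seed), kept_p, kept_m


def ccf_and_seeding_recovery(n_patients: int = 200, seed: int = 1) -> dict:
    """Cluster-CCF and seeding-mode recovery on a half-monoclonal,
    half-polyclonal cohort at default conditions (depth 200, purity 0.6,
    subclone CCFs >= 0.2 with >= 0.2 cluster separation).

    Returns mean absolute error of recovered cluster CCFs (true clones
    matched to their nearest recovered cluster), the fraction of
    patients with the true number of clusters, and seeding accuracy.
    """
    cfg = synthetic_cohort.SimConfig(seeding_mode="mixed", include_ai=False,
                                     include_expression=False)
    cohort, _ = synthetic_cohort.simulate_cohort(n_patients, cfg, seed)
    fit_seeds = synthetic_cohort.cohort_seeds(seed + 1, n_patients)
    abs_errors = []
    k_correct = 0
    mode_correct = 0
    for (bundle, truth), fseed in zip(cohort, fit_seeds):
        model, res, _, _ = _fit_bundle(bundle, fseed)
        if res.n_clusters == len(truth.clones):
            k_correct += 1
        for clone in truth.clones:
            tv = np.array([clone.ccf_by_sample[s] for s in model.sample_ids])
            best = min(
                res.clusters,
                key=lambda c: sum(
                    (c.mean_ccf_by_sample[s] - clone.ccf_by_sample[s]) ** 2
                    for s in model.sample_ids))
            bv = np.array([best.mean_ccf_by_sample[s]
                           for s in model.sample_ids])
            abs_errors.extend(np.abs(bv - tv))
        call = seeding_inference.call_seeding_mode(
            res.clusters, bundle.primary_id, bundle.metastasis_id)
        if call.mode == truth.seeding_mode:
            mode_correct += 1
    return {
        "mae": float(np.mean(abs_errors)),
        "k_accuracy": k_correct / n_patients,
        "seeding_accuracy": mode_correct / n_patients,
        "n": n_patients,
    }


def signature_noiseless_recovery() -> float:
    """L1 error of refitting an exact 0.6/0.4 two-signature mixture."""
    sigs = synthetic_cohort.synthetic_signatures(5)
    true_w = np.array([0.6, 0.4, 0.0, 0.0, 0.0])
    cat = signature_fit.catalog_from_channels([], "shared")
    cat.counts = sigs.values @ true_w * 1000
    cat.n_mutations = 1000
    res = signature_fit.fit_exposures(cat, sigs)
    return float(np.abs(res.weights.values - true_w).sum())


def signature_noisy_cosine_rate(n_replicates: int = 200, n_mutations: int = 500,
                                seed: int = 1) -> float:
    """Fraction of Poisson-noised 0.6/0.4 mixtures (n = 500 mutations)
    refitted with reconstruction cosine >= 0.95."""
    rng = np.random.default_rng(seed)
    sigs = synthetic_cohort.synthetic_signatures(5)
    mix = sigs.values @ np.array([0.6, 0.4, 0.0, 0.0, 0.0])
    ok = 0
    for _ in range(n_replicates):
        counts = rng.poisson(mix * n_mutations).astype(float)
        if counts.sum() == 0:
            continue
        cat = signature_fit.catalog_from_channels([], "shared")
        cat.counts = counts
        cat.n_mutations = int(counts.sum())
        if signature_fit.fit_exposures(cat, sigs).cosine >= 0.95:
            ok += 1
    return ok / n_replicates


def signature_delta_recovery(n_patients: int = 14, seed: int = 1) -> dict:
    """Recovery of the truncal-signature enrichment delta.

    Simulates monoclonal patients whose trunk mix carries +0.4 weight on
    the first signature relative to private clones, with enough
    mutations per clone that every category clears the >50-mutation
    eligibility floor, then measures the fitted shared-minus-private
    contribution difference.
    """
    cfg = synthetic_cohort.SimConfig(
        seeding_mode="monoclonal", mutations_per_clone=150,
        include_ai=False, include_expression=False)
    sigs = synthetic_cohort.synthetic_signatures(cfg.n_signatures)
    cohort, _ = synthetic_cohort.simulate_cohort(n_patients, cfg, seed,
                                                 signatures=sigs)
    per_patient = {}
    truth_delta = None
    for bundle, truth in cohort:
        if truth_delta is None:
            truth_delta = float(truth.category_mixes["shared"][0]
                                - truth.category_mixes["primary_only"][0])
        _, _, kept_p, kept_m = _fit_bundle(bundle, 0)
        part = seeding_inference.partition_mutations(
            kept_p, kept_m, bundle.mutations_of(bundle.primary_id),
            bundle.mutations_of(bundle.metastasis_id))
        by_key = {m.key: m for m in bundle.mutations}
        cats = {}
        for cat_name, keys in (("shared", part.shared),
                               ("primary_only", part.primary_only),
                               ("metastasis_only", part.metastasis_only)):
            muts = [by_key[k] for k in keys]
            catalog = signature_fit.build_catalog(muts, cat_name)
            if catalog.counts.sum() == 0:
                break
            cats[cat_name] = signature_fit.fit_exposures(catalog, sigs)
        if len(cats) == 3:
            per_patient[bundle.patient_id] = cats
    table = signature_fit.compare_category_exposures(per_patient,
                                                     min_mutations=50)
    row = table.loc["SYN1"]
    fitted = float(row["mean_shared"] - row["mean_primary_only"])
    return {
        "fitted_delta": fitted,
        "true_delta": truth_delta,
        "error": abs(fitted - truth_delta),
        "n_eligible": int(row["n_patients"]),
    }


def ai_calibration(n_regions: int = 100_000, n_sites: int = 50,
                   seed: int = 1) -> dict:
    """Empirical size and power of the phase-concordance binomial test.

    Under the null the deviation direction at each informative site is a
    fair coin; the tested statistic is the majority-haplotype count.
    """
    rng = np.random.default_rng(seed)
    decisions = np.array([
        binomial_sharing_test(n_sites, k)[1]
        for k in range(n_sites // 2, n_sites + 1)])
    null = rng.binomial(n_sites, 0.5, size=n_regions)
    k_null = np.maximum(null, n_sites - null)
    type1 = float(decisions[k_null - n_sites // 2].mean())
    alt = rng.binomial(n_sites, 0.9, size=n_regions)
    k_alt = np.maximum(alt, n_sites - alt)
    power = float(decisions[k_alt - n_sites // 2].mean())
    return {
        "type1": type1,
        "power": power,
        "p_20_20": binomial_sharing_test(20, 20)[0],
        "p_20_15": binomial_sharing_test(20, 15)[0],
        "n": n_regions,
    }


def scna_adjustment_identity() -> float:
    """Max |adjusted log2 ratio - log2(CN/2)| over a purity x CN sweep of
    ratios generated by the purity-mixture model."""
    worst = 0.0
    for purity in np.linspace(0.2, 1.0, 9):
        for cn in (1, 2, 3, 4, 6):
            observed = np.log2(purity * cn / 2 + (1 - purity))
            adj = scna_concordance.purity_adjust(observed, purity)
            worst = max(worst, abs(adj - np.log2(cn / 2)))
    return float(worst)


def scna_trunk_proportion(seed: int = 1) -> dict:
    """Trunk-event proportion recovered from a synthetic pair built with
    60% trunk SCNA events."""
    cfg = synthetic_cohort.SimConfig(include_ai=False,
                                     include_expression=False)
    bundle, truth = synthetic_cohort.simulate_patient(cfg, seed)
    gm = synthetic_cohort.toy_gene_model()
    lp = scna_concordance.assign_gene_log2(
        [s for s in bundle.segments if s.sample_id == bundle.primary_id], gm)
    lm = scna_concordance.assign_gene_log2(
        [s for s in bundle.segments if s.sample_id == bundle.metastasis_id],
        gm)
    pair = scna_concordance.gene_calls_for_pair(lp, lm, cfg.purity,
                                                cfg.purity)
    _, props = scna_concordance.classify_scna_events(pair)
    return {"trunk_proportion": props["trunk"],
            "true_proportion": truth.scna_trunk_fraction}


def _boundary_mutation(**kw):
    base = dict(chrom="1", pos=100, ref="C", alt="A", sample_id="S1",
                t_depth=100, t_alt=20, n_depth=50, n_alt=0, pop_af=0.0)
    base.update(kw)
    return MutationRecord(**base)


#: 12 boundary cases of the filter policy and their expected dispositions
FILTER_BOUNDARY_TABLE = [
    (dict(t_depth=50, t_alt=3, pos=1), None),
    (dict(t_depth=49, t_alt=10, pos=2), "min_t_depth"),
    (dict(n_depth=30, pos=3), None),
    (dict(n_depth=29, pos=4), "min_n_depth"),
    (dict(t_depth=100, t_alt=5, pos=5), None),
    (dict(t_depth=100, t_alt=4, pos=6), "min_vaf_snv"),
    (dict(ref="A", alt="AT", t_depth=100, t_alt=10, pos=7), None),
    (dict(ref="A", alt="AT", t_depth=100, t_alt=8, pos=8), "min_vaf_indel"),
    (dict(n_depth=100, n_alt=0, pos=9), None),
    (dict(n_depth=100, n_alt=1, pos=10), "max_n_vaf"),
    (dict(pop_af=0.01, pos=11), None),
    (dict(pop_af=0.011, pos=12), "max_pop_af"),
]


def filter_boundary_accuracy() -> float:
    """Fraction of the 12-row boundary table with the expected keep/remove
    disposition and removal reason."""
    records = [_boundary_mutation(**kw) for kw, _ in FILTER_BOUNDARY_TABLE]
    kept, removed = variant_filtering.apply_filters(records)
    kept_pos = {m.pos for m in kept}
    reason_by_pos = {m.pos: r for m, r in removed}
    correct = 0
    for kw, expected in FILTER_BOUNDARY_TABLE:
        pos = kw["pos"]
        if expected is None:
            correct += pos in kept_pos
        else:
            correct += reason_by_pos.get(pos) == expected
    return correct / len(FILTER_BOUNDARY_TABLE)


def end_to_end(outdir, seed: int = 1, n_patients: int = 8) -> dict:
    """Default-cohort end-to-end run: max |observed - true| shared
    mutation fraction across patients, plus seeding accuracy."""
    cfg = pipeline.PipelineConfig(seed=seed, n_patients=n_patients,
                                  outdir=str(outdir))
    summary = pipeline.run_all(cfg)
    err = (summary["shared_fraction"]
           - summary["true_trunk_fraction"]).abs()
    return {
        "max_shared_fraction_error": float(err.max()),
        "seeding_accuracy": float(
            (summary["called_mode"] == summary["true_mode"]).mean()),
        "summary": summary,
    }
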