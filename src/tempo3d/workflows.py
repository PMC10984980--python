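"""End-to-end recovery experiments on synthetic data.

Each function generates a seeded dataset with known truth, runs the full
pipeline on it, and returns summary statistics.  They are the package's
own validation experiments: the test suite asserts on their outputs and
the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np

from . import matrix as tmx
from .compartments import call_compartments, classify_and_cluster_dynamics
from .matrix import ContactMatrix
from .regulome import (
    assign_targets,
    call_enhancers,
    classify_priming,
    classify_sites,
    functional_sites,
    log2fc,
    size_factors_background,
)
from .reproducibility import scc
from .simulate import TIME_POINTS, make_contact_map, make_regulome, make_timecourse
from .tads import align_borders, call_borders, insulation_score

__all__ = [
    "ice_balance_stats",
    "compartment_recovery",
    "dynamic_fraction_recovery",
    "tad_recovery",
    "scc_suite",
    "regulome_recovery",
]


def _pipeline_compartments(m: ContactMatrix, activity: np.ndarray):
    mi = tmx.ice_normalize(tmx.filter_bins(m))
    corr = tmx.correlation_matrix(tmx.distance_correct(mi))
    return call_compartments(corr, activity)


def ice_balance_stats(seed: int, n_bins: int = 200) -> dict:
    """Marginal CV and mass conservation of ICE on a random contact matrix."""
    rng = np.random.default_rng(seed)
    v = rng.poisson(20.0, size=(n_bins, n_bins)).astype(float) + 1.0
    v = np.triu(v) + np.triu(v, 1).T
    from .grid import GenomeGrid

    m = ContactMatrix(GenomeGrid({"chrR": n_bins * 100_000}, 100_000), "chrR", v)
    out = tmx.ice_normalize(m)
    s = out.values.sum(axis=1)[out.valid]
    return {
        "marginal_cv": float(s.std() / s.mean()),
        "mass_relative_error": float(abs(out.values.sum() - v.sum()) / v.sum()),
    }


def compartment_recovery(seed: int, comp_strength: float = 2.0) -> dict:
    """Sign agreement between inferred compartment labels and the planted
    checkerboard on one synthetic chromosome."""
    m, truth = make_contact_map(seed, comp_strength=comp_strength)
    labels = np.array(truth["labels"], dtype=float)
    prof = _pipeline_compartments(m, labels)
    ok = prof.valid
    agreement = float(np.mean(np.sign(prof.score[ok]) == labels[ok]))
    return {"sign_agreement": agreement, "n_bins": int(ok.sum())}


def dynamic_fraction_recovery(seed: int) -> dict:
    """Recovered fraction of dynamic compartment bins on a 6-point time
    course with 12.5% of bins planted to switch."""
    mats, truth = make_timecourse(seed)
    profiles = []
    for t, m in enumerate(mats):
        activity = np.array(truth["labels_per_tp"][t], dtype=float)
        profiles.append(_pipeline_compartments(m, activity))
    dyn = classify_and_cluster_dynamics(profiles)
    planted = len(truth["switch_bins"]) / truth["n_bins"]
    return {
        "dynamic_fraction": dyn.dynamic_fraction,
        "planted_fraction": planted,
        "n_bins": int(len(dyn.bins)),
    }


def tad_recovery(seed: int, junctions=(40, 80, 120, 160), tad_fold: float = 3.0) -> dict:
    """Junction recall (within one bin) and spurious-call fraction of the
    insulation border caller on a map with planted TAD blocks."""
    m, truth = make_contact_map(
        seed, n_bins=200, binsize=50_000, comp_strength=1.0,
        tad_fold=tad_fold, junctions=junctions,
    )
    mi = tmx.ice_normalize(tmx.filter_bins(m))
    borders = call_borders(insulation_score(mi))
    # the boundary at the right edge of bin j-1 separates TADs meeting at junction j
    expected = [j - 1 for j in truth["junctions"]]
    hits = sum(any(abs(b.bin_index - e) <= 1 for b in borders) for e in expected)
    spurious = sum(all(abs(b.bin_index - e) > 1 for e in expected) for b in borders)
    return {
        "junctions_recovered": int(hits),
        "junctions_planted": len(expected),
        "spurious_fraction": float(spurious / len(borders)) if borders else 0.0,
        "n_called": len(borders),
    }


def scc_suite(seed: int) -> dict:
    """Self, replicate and permuted-map stratum-adjusted correlations."""
    a, _ = make_contact_map(seed)
    b, _ = make_contact_map(seed + 1)  # independent Poisson draw, same truth
    rng = np.random.default_rng(seed)
    n = 200
    v = rng.poisson(15.0, size=(n, n)).astype(float)
    v = np.triu(v) + np.triu(v, 1).T
    from .grid import GenomeGrid

    grid = GenomeGrid({"chrR": n * 100_000}, 100_000)
    m = ContactMatrix(grid, "chrR", v)
    perm = rng.permutation(n)
    pv = m.values[np.ix_(perm, perm)]
    p = ContactMatrix(grid, "chrR", (pv + pv.T) / 2)
    return {
        "self": float(scc(a, a)),
        "replicates": float(scc(a, b)),
        "permuted": float(scc(m, p)),
    }


def regulome_recovery(seed: int) -> dict:
    """Precision/recall of distal target assignment and primed-fraction
    recovery on the fully synthetic regulome."""
    data = make_regulome(seed)
    sites = functional_sites(data.p53_peaks, data.k27ac)
    enhancers = call_enhancers(
        data.k4me1, data.k27ac, data.promoters, time_points=TIME_POINTS
    )
    classified = classify_sites(sites, data.promoters, enhancers)
    sf = size_factors_background(
        data.background_counts, data.background_bins, data.enriched_regions
    )
    fc = log2fc(data.promoter_counts, sf, data.samples_a, data.samples_b)
    assignments = classify_priming(
        assign_targets(
            classified, data.promoters, enhancers, data.interactions,
            fc.to_dict(), "1h", genes=data.genes,
        ),
        data.interactions,
    )
    distal = [a for a in assignments if a.mode == "distal"]
    predicted = {(a.site.peak.start, a.gene_id) for a in distal}
    planted = {(t["site_start"], t["gene"]) for t in data.truth["planted_targets"]}
    tp = len(predicted & planted)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(planted)
    primed = float(np.mean([a.primed for a in distal])) if distal else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "primed_fraction": primed,
        "planted_primed_fraction": data.truth["primed_fraction"],
        "n_distal": len(distal),
        "size_factor_max_relative_error": float(
            np.max(
                np.abs(
                    sf.to_numpy()
                    / (
                        np.array(data.truth["scale_factors"])
                        / np.exp(np.log(data.truth["scale_factors"]).mean())
                    )
                    - 1
                )
            )
        ),
    }
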