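"""End-to-end drivers tying forcing, estimation, simulation and hypothesis
testing together. The CLI is a thin wrapper over these."""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

from .forcing import DyadData, HaploidGenotypes, intersect_dyad
from .plink_io import AlleleFrequencyTable
from .relatedness import RelatednessClass
from .rxy import RxyEstimate, rxy_forced
from .simulate import EmpiricalDistribution, simulate_class_distribution
from .trio import DYAD_KEYS, TrioReport, evaluate_trio

__all__ = ["pairwise_rxy", "calibrated_fits", "analyze_trio"]


def pairwise_rxy(
    genotypes: Sequence[HaploidGenotypes],
    freqs: AlleleFrequencyTable,
) -> list[tuple[str, str, RxyEstimate]]:
    """Forced-homozygote Rxy for every pair of individuals."""
    out = []
    for gx, gy in combinations(genotypes, 2):
        est = rxy_forced(intersect_dyad(gx, gy, freqs))
        out.append((gx.sample_id, gy.sample_id, est))
    return out


def calibrated_fits(
    dyads: Mapping[str, DyadData],
    n_dyads: int,
    seed: int,
    sigma_floor: float = 1e-6,
) -> tuple[dict[tuple[str, RelatednessClass], tuple[float, float]], dict[str, dict[str, EmpiricalDistribution]]]:
    """Simulate the nine dyad-specific class distributions and fit normals.

    Each dyad's distributions are simulated on that dyad's own shared-locus
    panel (its loci and frequencies), since the three shared-SNP sets
    differ. Returns the (dyad, class) -> (mu, sigma) mapping plus the full
    distributions for reporting/plotting.
    """
    fits: dict[tuple[str, RelatednessClass], tuple[float, float]] = {}
    dists: dict[str, dict[str, EmpiricalDistribution]] = {}
    for key, dyad in dyads.items():
        panel = AlleleFrequencyTable(dyad.loci)
        dists[key] = {}
        for cls in RelatednessClass:
            d = simulate_class_distribution(
                cls,
                panel,
                n_dyads=n_dyads,
                seed=seed,
                sigma_floor=sigma_floor,
            )
            fits[(key, cls)] = (d.mu, d.sigma)
            dists[key][cls.label] = d
    return fits, dists


def analyze_trio(
    ga: HaploidGenotypes,
    gb: HaploidGenotypes,
    gc: HaploidGenotypes,
    freqs: AlleleFrequencyTable,
    n_dyads: int = 2000,
    seed: int = 0,
    sigma_floor: float = 1e-6,
) -> tuple[TrioReport, dict[str, dict[str, EmpiricalDistribution]]]:
    """Full trio analysis from forced genotypes.

    Intersects each dyad, computes observed forced Rxy, simulates the nine
    class distributions on each dyad's shared panel, and evaluates the
    eleven-hypothesis set.
    """
    dyads = {
        "ab": intersect_dyad(ga, gb, freqs),
        "ac": intersect_dyad(ga, gc, freqs),
        "bc": intersect_dyad(gb, gc, freqs),
    }
    observed = {k: rxy_forced(d).value for k, d in dyads.items()}
    n_loci = {k: d.n_loci for k, d in dyads.items()}
    fits, dists = calibrated_fits(dyads, n_dyads=n_dyads, seed=seed, sigma_floor=sigma_floor)
    report = evaluate_trio(
        sample_ids=(ga.sample_id, gb.sample_id, gc.sample_id),
        observed=observed,
        fits=fits,
        n_loci=n_loci,
    )
    return report, dists
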