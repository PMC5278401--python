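"""Pedigree simulation of dyads for calibrating forced-homozygote Rxy.

Observed coefficients are interpreted against empirical distributions built
by Monte Carlo: unrelated individuals are drawn from Hardy-Weinberg
genotype frequencies at the panel's allele frequencies, relatives are
produced by Mendelian gene-dropping (one allele from each parent, loci
independent), and the final dyad members are forced homozygous exactly like
the real data. Full siblings realize first-order relatedness, half siblings
second order. Repeating this for thousands of dyads and fitting a normal
gives the (mu, sigma) used by the trio hypothesis machinery.

Pedigrees are simulated fully diploid; homozygosity is forced only on the
dyad members that are scored (a literal parents-forced-first variant is
available behind ``force_parents`` for comparison). Loci are treated as
unlinked, appropriate for a sparse genome-wide SNP panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import substream
from .errors import KinforceError
from .forcing import DiploidGenotypes, HaploidGenotypes
from .plink_io import AlleleFrequencyTable
from .relatedness import RelatednessClass
from .rxy import rxy_forced_indices, rxy_general_indices
from .trio import fit_normal

__all__ = [
    "DEFAULT_N_DYADS",
    "EmpiricalDistribution",
    "sample_unrelated",
    "mendelian_offspring",
    "simulate_dyad",
    "simulate_dyad_diploid",
    "simulate_class_distribution",
]

DEFAULT_N_DYADS = 2000
SIGMA_FLOOR = 1e-6


@dataclass
class EmpiricalDistribution:
    """Simulated Rxy samples for one relatedness class, with a normal fit."""

    class_label: str
    samples: np.ndarray
    n_dyads: int
    mu: float
    sigma: float
    n_loci: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.n_dyads < 2 or len(self.samples) != self.n_dyads:
            raise KinforceError("an empirical distribution needs >= 2 dyad samples")
        if self.sigma <= 0:
            raise KinforceError("sigma must be positive (sigma_floor applies)")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "class": self.class_label,
            "n_dyads": self.n_dyads,
            "n_loci": self.n_loci,
            "seed": self.seed,
            "mu": self.mu,
            "sigma": self.sigma,
            "samples": [round(float(s), 8) for s in self.samples],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "EmpiricalDistribution":
        d = json.loads(Path(path).read_text())
        return cls(
            class_label=d["class"],
            samples=np.asarray(d["samples"], dtype=float),
            n_dyads=d["n_dyads"],
            mu=d["mu"],
            sigma=d["sigma"],
            n_loci=d["n_loci"],
            seed=d.get("seed"),
        )


# ---------------------------------------------------------------------------
# index-coded core (0 = allele1, carried with probability freq1)


def _panel_p1(freqs: AlleleFrequencyTable) -> np.ndarray:
    p1 = np.asarray([loc.freq1 for loc in freqs], dtype=float)
    if np.any(p1 <= 0.0) or np.any(p1 >= 1.0) or np.any(np.isnan(p1)):
        raise KinforceError("simulation panel needs every freq1 strictly inside (0, 1)")
    return p1


def _hwe_individual(p1: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(L, 2) allele indices: each allele is allele1 with probability p1."""
    return (rng.random((p1.shape[0], 2)) >= p1[:, None]).astype(np.int8)


def _drop_one(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per locus, chosen uniformly from the pair."""
    pick = rng.integers(0, 2, parent.shape[0])
    return parent[np.arange(parent.shape[0]), pick]


def _offspring(p1g: np.ndarray, p2g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.stack([_drop_one(p1g, rng), _drop_one(p2g, rng)], axis=1)


def _force(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return _drop_one(g, rng)


def _simulate_dyad_diploid_idx(
    cls: RelatednessClass,
    p1: np.ndarray,
    rng: np.random.Generator,
    first_order_parent_offspring: bool = False,
    force_parents: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Diploid (L, 2) genotypes of both dyad members, per class recipe."""

    def founder() -> np.ndarray:
        g = _hwe_individual(p1, rng)
        if force_parents:
            a = _force(g, rng)
            g = np.stack([a, a], axis=1)
        return g

    if cls is RelatednessClass.UNRELATED:
        return founder(), founder()
    if cls is RelatednessClass.FIRST_ORDER:
        pa, pb = founder(), founder()
        if first_order_parent_offspring:
            return pa, _offspring(pa, pb, rng)
        return _offspring(pa, pb, rng), _offspring(pa, pb, rng)
    if cls is RelatednessClass.SECOND_ORDER:
        shared, pb, pc = founder(), founder(), founder()
        return _offspring(shared, pb, rng), _offspring(shared, pc, rng)
    raise KinforceError(f"unknown relatedness class {cls!r}")


def _idx_to_diploid(
    sample_id: str, g: np.ndarray, freqs: AlleleFrequencyTable
) -> DiploidGenotypes:
    calls = {}
    for loc, (i, j) in zip(freqs, g):
        pair = (loc.allele1, loc.allele2)
        calls[loc.id] = (pair[int(i)], pair[int(j)])
    return DiploidGenotypes(sample_id=sample_id, calls=calls)


def _idx_to_haploid(
    sample_id: str, h: np.ndarray, freqs: AlleleFrequencyTable
) -> HaploidGenotypes:
    alleles = {
        loc.id: (loc.allele1, loc.allele2)[int(i)] for loc, i in zip(freqs, h)
    }
    return HaploidGenotypes(sample_id=sample_id, alleles=alleles)


# ---------------------------------------------------------------------------
# public operations


def sample_unrelated(
    freqs: AlleleFrequencyTable,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> DiploidGenotypes:
    """Draw one individual from Hardy-Weinberg proportions at the panel frequencies."""
    p1 = _panel_p1(freqs)
    return _idx_to_diploid(sample_id, _hwe_individual(p1, rng), freqs)


def mendelian_offspring(
    p1: DiploidGenotypes,
    p2: DiploidGenotypes,
    rng: np.random.Generator,
    sample_id: str = "offspring",
) -> DiploidGenotypes:
    """Gene-drop one offspring: one uniformly chosen allele from each parent per locus."""
    if list(p1.calls) != list(p2.calls):
        raise KinforceError("parents are on different locus panels")
    calls = {}
    for lid in p1.calls:
        ga, gb = p1.calls[lid], p2.calls[lid]
        calls[lid] = (ga[int(rng.integers(2))], gb[int(rng.integers(2))])
    return DiploidGenotypes(sample_id=sample_id, calls=calls)


def simulate_dyad(
    cls: RelatednessClass,
    freqs: AlleleFrequencyTable,
    rng: np.random.Generator,
    first_order_parent_offspring: bool = False,
    force_parents: bool = False,
) -> tuple[HaploidGenotypes, HaploidGenotypes]:
    """Simulate one dyad of the given class, forced homozygous.

    UNRELATED draws two independent Hardy-Weinberg individuals; FIRST_ORDER
    breeds two full siblings from the same two founders (or a
    parent-offspring pair when requested); SECOND_ORDER breeds half
    siblings sharing one founder. Both members are then reduced to one
    allele per locus.
    """
    p1 = _panel_p1(freqs)
    gx, gy = _simulate_dyad_diploid_idx(
        cls, p1, rng, first_order_parent_offspring, force_parents
    )
    hx, hy = _force(gx, rng), _force(gy, rng)
    return (
        _idx_to_haploid(f"{cls.label}_x", hx, freqs),
        _idx_to_haploid(f"{cls.label}_y", hy, freqs),
    )


def simulate_dyad_diploid(
    cls: RelatednessClass,
    freqs: AlleleFrequencyTable,
    rng: np.random.Generator,
    first_order_parent_offspring: bool = False,
) -> tuple[DiploidGenotypes, DiploidGenotypes]:
    """Simulate one dyad and keep full diploid genotypes (no forcing)."""
    p1 = _panel_p1(freqs)
    gx, gy = _simulate_dyad_diploid_idx(cls, p1, rng, first_order_parent_offspring)
    return (
        _idx_to_diploid(f"{cls.label}_x", gx, freqs),
        _idx_to_diploid(f"{cls.label}_y", gy, freqs),
    )


def simulate_class_distribution(
    cls: RelatednessClass,
    freqs: AlleleFrequencyTable,
    n_dyads: int = DEFAULT_N_DYADS,
    seed: int = 0,
    forced: bool = True,
    sigma_floor: float = SIGMA_FLOOR,
    first_order_parent_offspring: bool = False,
) -> EmpiricalDistribution:
    """Empirical Rxy distribution for one class on one frequency panel.

    Runs ``n_dyads`` independent dyad simulations, scores each with the
    forced-homozygote estimator (or the diploid estimator when
    ``forced=False``) against the generating frequencies, and fits a normal
    by maximum likelihood. The stream is a substream named by the class and
    mode, so reruns with the same seed are bit-identical and the three
    classes are independent.
    """
    if n_dyads < 2:
        raise KinforceError("n_dyads must be >= 2")
    p1 = _panel_p1(freqs)
    rng = substream(seed, "class_distribution", cls.label, "forced" if forced else "diploid")
    samples = np.empty(n_dyads)
    for k in range(n_dyads):
        gx, gy = _simulate_dyad_diploid_idx(cls, p1, rng, first_order_parent_offspring)
        if forced:
            hx, hy = _force(gx, rng), _force(gy, rng)
            samples[k] = rxy_forced_indices(hx, hy, p1).value
        else:
            samples[k] = rxy_general_indices(gx, gy, p1).value
    mu, sigma = fit_normal(samples, sigma_floor=sigma_floor)
    return EmpiricalDistribution(
        class_label=cls.label,
        samples=samples,
        n_dyads=n_dyads,
        mu=mu,
        sigma=sigma,
        n_loci=len(freqs),
        seed=seed,
    )


def plot_distributions(
    dists: Sequence[EmpiricalDistribution],
    path: str | Path,
    observed: float | None = None,
) -> None:
    """Histogram the class distributions (one panel), optionally marking an
    observed coefficient."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"UNRELATED": "#3465a4", "SECOND_ORDER": "#4e9a06", "FIRST_ORDER": "#cc0000"}
    fig, ax = plt.subplots(figsize=(7, 4))
    for d in dists:
        ax.hist(
            d.samples,
            bins=50,
            alpha=0.6,
            label=f"{d.class_label} (mu={d.mu:.3f}, sigma={d.sigma:.3f})",
            color=colors.get(d.class_label),
        )
    if observed is not None:
        ax.axvline(observed, color="goldenrod", lw=2, label=f"observed {observed:.4f}")
    ax.set_xlabel("forced-homozygote Rxy")
    ax.set_ylabel("simulated dyads")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
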