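"""The Queller-Goodnight symmetric relatedness estimator Rxy.

For a dyad (x, y) scored at L biallelic loci against reference allele
frequencies p, the estimator is a ratio of sums (never a mean of per-locus
ratios). With x = (a, b) and y = (c, d) at one locus, the focal-x terms are

    num_x = 1/2 [I(a=c) + I(a=d) + I(b=c) + I(b=d)] - p_a - p_b
    den_x = 1 + I(a=b) - p_a - p_b

and symmetrically for focal y; the estimate is

    Rxy = (sum_l num_x + num_y) / (sum_l den_x + den_y).

Under forced homozygosity (a=b, c=d) the per-locus contributions reduce to
num = 2 I(a=c) - p_a - p_c and den = 2 - p_a - p_c, which ``rxy_forced``
evaluates directly; ``rxy_general`` on duplicated-allele input gives exactly
the same value.

Reference frequencies are used exactly as supplied (an external panel such
as 1000 Genomes EUR); no within-sample re-estimation, no focal-pair
exclusion, no small-sample bias correction. The value is reported raw and
may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EstimatorError, NoSharedLociError
from .forcing import DiploidGenotypes, DyadData
from .plink_io import MISSING, AlleleFrequencyTable, Locus

__all__ = ["RxyEstimate", "rxy_forced", "rxy_general", "write_rxy_table"]

# den_x + den_y can vanish only to rounding when both individuals are
# heterozygous with p_a + p_b = 1; such loci carry no information.
_DEN_EPS = 1e-9


@dataclass(frozen=True)
class RxyEstimate:
    """An Rxy value with its accumulated numerator/denominator and locus count.

    ``value`` equals ``num_sum / den_sum`` exactly; it is not clamped to
    [0, 1] and may legitimately be negative. ``n_uninformative`` counts loci
    skipped because their denominator contribution was zero.
    """

    value: float
    n_loci: int
    num_sum: float
    den_sum: float
    n_uninformative: int = 0


def _finalize(num: np.ndarray, den: np.ndarray, label: str) -> RxyEstimate:
    informative = np.abs(den) > _DEN_EPS
    n_skip = int((~informative).sum())
    num_sum = float(num[informative].sum())
    den_sum = float(den[informative].sum())
    if den_sum <= 0.0:
        raise EstimatorError(f"{label}: denominator sum {den_sum} <= 0 (no informative loci)")
    return RxyEstimate(
        value=num_sum / den_sum,
        n_loci=int(informative.sum()),
        num_sum=num_sum,
        den_sum=den_sum,
        n_uninformative=n_skip,
    )


def _haploid_terms(
    same: np.ndarray, pa: np.ndarray, pc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forced-homozygote per-locus contributions (both focal terms collapsed)."""
    num = 2.0 * same - pa - pc
    den = 2.0 - pa - pc
    return num, den


def _diploid_terms(
    gx: np.ndarray, gy: np.ndarray, p1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric per-locus contributions for diploid index genotypes.

    ``gx``, ``gy`` are (L, 2) arrays of allele indices (0 = allele1), ``p1``
    the (L,) frequency of allele1.
    """
    freqs = np.stack([p1, 1.0 - p1], axis=1)  # (L, 2)
    rows = np.arange(gx.shape[0])
    pa = freqs[rows, gx[:, 0]]
    pb = freqs[rows, gx[:, 1]]
    pc = freqs[rows, gy[:, 0]]
    pd = freqs[rows, gy[:, 1]]
    share = np.zeros(gx.shape[0])
    for i in (0, 1):
        for j in (0, 1):
            share += gx[:, i] == gy[:, j]
    num_x = 0.5 * share - pa - pb
    num_y = 0.5 * share - pc - pd
    den_x = 1.0 + (gx[:, 0] == gx[:, 1]) - pa - pb
    den_y = 1.0 + (gy[:, 0] == gy[:, 1]) - pc - pd
    return num_x + num_y, den_x + den_y


def rxy_forced(d: DyadData) -> RxyEstimate:
    """Rxy for a forced-homozygote dyad (one allele per individual per locus)."""
    ax = np.asarray(d.allele_x)
    ay = np.asarray(d.allele_y)
    a1 = np.asarray([loc.allele1 for loc in d.loci])
    p1 = np.asarray([loc.freq1 for loc in d.loci], dtype=float)
    pa = np.where(ax == a1, p1, 1.0 - p1)
    pc = np.where(ay == a1, p1, 1.0 - p1)
    num, den = _haploid_terms((ax == ay).astype(float), pa, pc)
    return _finalize(num, den, f"{d.id_x} x {d.id_y}")


def rxy_forced_indices(hx: np.ndarray, hy: np.ndarray, p1: np.ndarray) -> RxyEstimate:
    """Index-coded fast path used by the simulator (0 = allele1 carried).

    Arithmetically identical to :func:`rxy_forced` on the equivalent
    character-coded dyad.
    """
    freqs = np.stack([p1, 1.0 - p1], axis=1)
    rows = np.arange(len(hx))
    num, den = _haploid_terms((hx == hy).astype(float), freqs[rows, hx], freqs[rows, hy])
    return _finalize(num, den, "dyad")


def rxy_general(
    gx: DiploidGenotypes,
    gy: DiploidGenotypes,
    freqs: AlleleFrequencyTable,
) -> RxyEstimate:
    """Symmetric diploid Rxy on the shared called loci of two individuals.

    Loci missing in either individual, absent from the panel, monomorphic in
    the panel, or carrying alleles outside the locus allele pair are
    excluded. On duplicated-allele (forced) input this reduces exactly to
    :func:`rxy_forced`.
    """
    called_x = gx.called_ids()
    called_y = gy.called_ids()
    shared = called_x & called_y
    if not shared:
        raise NoSharedLociError(f"{gx.sample_id} x {gy.sample_id}: no shared loci")
    gx_idx: list[tuple[int, int]] = []
    gy_idx: list[tuple[int, int]] = []
    p1: list[float] = []
    for loc in freqs:
        if loc.id not in shared:
            continue
        if loc.freq1 is None or not (0.0 < loc.freq1 < 1.0):
            continue
        code = {loc.allele1: 0, loc.allele2: 1}
        try:
            xa = tuple(code[a] for a in gx.calls[loc.id])
            ya = tuple(code[a] for a in gy.calls[loc.id])
        except KeyError:
            continue  # allele outside the panel pair: excluded, never recoded
        gx_idx.append(xa)  # type: ignore[arg-type]
        gy_idx.append(ya)  # type: ignore[arg-type]
        p1.append(loc.freq1)
    if not p1:
        raise NoSharedLociError(
            f"{gx.sample_id} x {gy.sample_id}: no usable shared loci after filtering"
        )
    num, den = _diploid_terms(np.asarray(gx_idx), np.asarray(gy_idx), np.asarray(p1))
    return _finalize(num, den, f"{gx.sample_id} x {gy.sample_id}")


def rxy_general_indices(
    gx: np.ndarray, gy: np.ndarray, p1: np.ndarray
) -> RxyEstimate:
    """Index-coded diploid fast path used by the simulator."""
    num, den = _diploid_terms(np.asarray(gx), np.asarray(gy), np.asarray(p1))
    return _finalize(num, den, "dyad")


def write_rxy_table(
    rows: Iterable[tuple[str, str, RxyEstimate]], path: str | Path
) -> None:
    """Write one TSV row per dyad: id_x, id_y, n_loci, rxy."""
    with open(path, "w") as fh:
        fh.write("id_x\tid_y\tn_loci\trxy\n")
        for id_x, id_y, est in rows:
            fh.write(f"{id_x}\t{id_y}\t{est.n_loci}\t{est.value:.6f}\n")
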