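"""Synthetic fixture generation: frequency panels and low-coverage trios.

Every pipeline stage can be exercised without any external download. The
frequency generator emulates an ascertained common-SNP array: minor allele
frequencies uniform on a stated band (default 0.05-0.5). The trio generator
realizes a pedigree for a requested relatedness structure, then emulates
very low-coverage shotgun sequencing by Bernoulli-thinning each
individual's loci (at ~0.04-0.1X virtually every covered site has a single
read, so per-locus coverage is modelled as hit/no-hit with an optional
two-read fraction) and writes pileup TSVs plus a truth record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._rng import substream
from .errors import KinforceError
from .plink_io import AlleleFrequencyTable, Locus, PileupSiteCalls, write_frq, write_pileup_calls
from .relatedness import RelatednessClass
from .simulate import _hwe_individual, _offspring, _panel_p1

__all__ = [
    "RunConfig",
    "CoverageModel",
    "TrioTruth",
    "generate_frequency_fixture",
    "generate_trio_fixture",
]

_BASES = "ACGT"


@dataclass
class RunConfig:
    """Run-level knobs shared by the CLI subcommands."""

    seed: int = 0
    min_qual: int = 30
    n_dyads: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    sigma_floor: float = 1e-6
    prior: list[float] | None = None
    hypothesis_set: str = "table11"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_low < self.maf_high <= 0.5):
            raise KinforceError("need 0 < maf_low < maf_high <= 0.5")
        if self.n_dyads < 2:
            raise KinforceError("n_dyads must be >= 2")
        if self.min_qual < 0:
            raise KinforceError("min_qual must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class CoverageModel:
    """Low-coverage read sampling: per-locus hit probability and quality model.

    ``hit_prob`` is the chance a locus receives any read (Bernoulli per locus
    per individual); ``depth2_prob`` the chance a covered locus has a second
    read. Qualities are rounded normal(qual_mean, qual_sd) clipped to [2, 41],
    so a few calls fall under the usual phred-30 threshold.
    """

    hit_prob: float = 0.1
    depth2_prob: float = 0.02
    qual_mean: float = 37.0
    qual_sd: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.hit_prob <= 1.0):
            raise KinforceError("hit_prob must be in (0, 1]")
        if not (0.0 <= self.depth2_prob <= 1.0):
            raise KinforceError("depth2_prob must be in [0, 1]")


@dataclass
class TrioTruth:
    """What the generator actually simulated, for reconciling downstream counts."""

    structure: tuple[str, str, str]
    sample_ids: tuple[str, str, str]
    seed: int
    n_panel_loci: int
    genotypes: dict[str, dict[str, str]]  # sample -> locus id -> "AG"
    covered: dict[str, list[str]]  # sample -> covered locus ids
    shared_covered: dict[str, int]  # dyad key -> |covered_x & covered_y|

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["structure"] = list(self.structure)
        d["sample_ids"] = list(self.sample_ids)
        Path(path).write_text(json.dumps(d) + "\n")


def generate_frequency_fixture(
    n_loci: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
    path: str | Path | None = None,
) -> AlleleFrequencyTable:
    """Synthetic biallelic panel: loci rs1..rsN, MAF ~ U(maf_low, maf_high).

    ``freq1`` is the minor-allele frequency (allele1 is the minor allele, as
    in a PLINK .frq). Byte-reproducible for a fixed seed; optionally written
    to ``path`` as .frq.
    """
    if n_loci < 1:
        raise KinforceError("n_loci must be >= 1")
    if not (0.0 < maf_low < maf_high <= 0.5):
        raise KinforceError("need 0 < maf_low < maf_high <= 0.5")
    rng = substream(seed, "frequency_fixture", n_loci)
    mafs = rng.uniform(maf_low, maf_high, n_loci)
    pair_idx = rng.integers(0, 4, (n_loci, 2))
    # resample collisions so the two alleles always differ
    while np.any(pair_idx[:, 0] == pair_idx[:, 1]):
        clash = pair_idx[:, 0] == pair_idx[:, 1]
        pair_idx[clash, 1] = rng.integers(0, 4, int(clash.sum()))
    loci = [
        Locus(
            id=f"rs{i + 1}",
            chrom=str(i % 22 + 1),
            pos=(i // 22 + 1) * 1000,
            allele1=_BASES[int(a)],
            allele2=_BASES[int(b)],
            freq1=float(m),
        )
        for i, (m, (a, b)) in enumerate(zip(mafs, pair_idx))
    ]
    table = AlleleFrequencyTable(loci)
    if path is not None:
        write_frq(table, path)
    return table


_STRUCTURES: dict[tuple[str, str, str], str] = {
    ("UNRELATED", "UNRELATED", "UNRELATED"): "three founders",
    ("SECOND_ORDER", "SECOND_ORDER", "FIRST_ORDER"): "A half-sib of full siblings B, C",
    ("FIRST_ORDER", "FIRST_ORDER", "FIRST_ORDER"): "three full siblings",
    ("UNRELATED", "UNRELATED", "FIRST_ORDER"): "outsider A, full siblings B, C",
}


def _simulate_pedigree(
    structure: tuple[str, str, str],
    p1: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Diploid index genotypes for A, B, C realizing the dyad-class triple."""
    if structure == ("UNRELATED", "UNRELATED", "UNRELATED"):
        return [_hwe_individual(p1, rng) for _ in range(3)]
    if structure == ("SECOND_ORDER", "SECOND_ORDER", "FIRST_ORDER"):
        shared, p2, p3 = (_hwe_individual(p1, rng) for _ in range(3))
        a = _offspring(shared, p3, rng)
        b = _offspring(shared, p2, rng)
        c = _offspring(shared, p2, rng)
        return [a, b, c]
    if structure == ("FIRST_ORDER", "FIRST_ORDER", "FIRST_ORDER"):
        pa, pb = (_hwe_individual(p1, rng) for _ in range(2))
        return [_offspring(pa, pb, rng) for _ in range(3)]
    if structure == ("UNRELATED", "UNRELATED", "FIRST_ORDER"):
        pa, pb = (_hwe_individual(p1, rng) for _ in range(2))
        return [_hwe_individual(p1, rng), _offspring(pa, pb, rng), _offspring(pa, pb, rng)]
    raise KinforceError(
        f"unsupported trio structure {structure}; supported: {sorted(_STRUCTURES)}"
    )


def generate_trio_fixture(
    structure: tuple[str, str, str],
    freqs: AlleleFrequencyTable,
    coverage: CoverageModel | Sequence[CoverageModel],
    seed: int,
    outdir: str | Path,
    sample_ids: tuple[str, str, str] = ("A", "B", "C"),
) -> TrioTruth:
    """Simulate a pedigree, thin by the coverage model, write pileups + truth.

    ``structure`` names the relatedness classes of the dyads (A-B, A-C, B-C).
    ``coverage`` is one model for all three individuals or one per
    individual. Writes ``<sample>.pileup.tsv`` per individual and
    ``truth.json`` to ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covs = list(coverage) if isinstance(coverage, (list, tuple)) else [coverage] * 3
    if len(covs) != 3:
        raise KinforceError("need one coverage model or exactly three")
    p1 = _panel_p1(freqs)
    rng = substream(seed, "trio_fixture", *structure)
    genos = _simulate_pedigree(tuple(structure), p1, rng)  # type: ignore[arg-type]

    genotypes: dict[str, dict[str, str]] = {}
    covered: dict[str, list[str]] = {}
    for sid, g, cov in zip(sample_ids, genos, covs):
        loci = list(freqs)
        genotypes[sid] = {
            loc.id: (loc.allele1, loc.allele2)[int(i)] + (loc.allele1, loc.allele2)[int(j)]
            for loc, (i, j) in zip(loci, g)
        }
        hits = rng.random(len(loci)) < cov.hit_prob
        sites: list[PileupSiteCalls] = []
        ids: list[str] = []
        for loc, (i, j), hit in zip(loci, g, hits):
            if not hit:
                continue
            depth = 1 + int(rng.random() < cov.depth2_prob)
            pair = ((loc.allele1, loc.allele2)[int(i)], (loc.allele1, loc.allele2)[int(j)])
            bases = tuple(pair[int(rng.integers(2))] for _ in range(depth))
            quals = tuple(
                int(np.clip(round(rng.normal(cov.qual_mean, cov.qual_sd)), 2, 41))
                for _ in range(depth)
            )
            sites.append(PileupSiteCalls(locus_id=loc.id, bases=bases, quals=quals))
            ids.append(loc.id)
        covered[sid] = ids
        write_pileup_calls(sites, outdir / f"{sid}.pileup.tsv")

    a, b, c = sample_ids
    shared = {
        "ab": len(set(covered[a]) & set(covered[b])),
        "ac": len(set(covered[a]) & set(covered[c])),
        "bc": len(set(covered[b]) & set(covered[c])),
    }
    truth = TrioTruth(
        structure=tuple(structure),  # type: ignore[arg-type]
        sample_ids=sample_ids,
        seed=seed,
        n_panel_loci=len(freqs),
        genotypes=genotypes,
        covered=covered,
        shared_covered=shared,
    )
    truth.to_json(outdir / "truth.json")
    return truth
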