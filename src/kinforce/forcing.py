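"""Forced-homozygote reduction and dyad intersection.

Very low-coverage data (here, ~0.04-0.1X shotgun) yields mostly single-read
SNP calls, so heterozygotes cannot be observed. Rather than mix true
heterozygous calls with possibly-false homozygous ones, every locus is
reduced to a single allele: for read pileups one qualifying call is chosen
at random; for diploid genotypes one of the two alleles is dropped at
random. The retained allele is conceptually duplicated ("forced homozygote")
so the data remain diploid-shaped for downstream tools, and the expected
relatedness coefficient halves.

Missingness is never imputed, and alleles inconsistent with the frequency
panel are excluded and counted, never recoded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rng import substream
from .errors import FormatError, NoSharedLociError
from .plink_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    Locus,
    PileupSiteCalls,
)

__all__ = [
    "DEFAULT_MIN_QUAL",
    "HaploidGenotypes",
    "DiploidGenotypes",
    "DyadData",
    "force_site",
    "force_dataset",
    "force_diploid",
    "intersect_dyad",
    "haploid_to_dataset",
    "dataset_to_diploid",
]

DEFAULT_MIN_QUAL = 30


@dataclass
class DiploidGenotypes:
    """One individual's diploid calls: locus id -> ordered allele pair.

    ``"0"`` in either slot marks a missing call.
    """

    sample_id: str
    calls: dict[str, tuple[str, str]]

    def called_ids(self) -> set[str]:
        return {
            lid
            for lid, (a, b) in self.calls.items()
            if a != MISSING and b != MISSING
        }


@dataclass
class HaploidGenotypes:
    """One individual's pseudo-haploid calls: locus id -> single allele.

    ``n_dropped`` counts input sites that yielded no call during forcing, so
    that called + dropped equals the number of sites seen.
    """

    sample_id: str
    alleles: dict[str, str]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass
class DyadData:
    """The per-pair intersection of called loci, with frequencies attached.

    Only loci called in both individuals, present in the frequency panel
    with freq1 strictly inside (0, 1), and with both observed alleles in the
    locus allele set are kept. ``exclusions`` counts the shared loci removed
    for each reason.
    """

    id_x: str
    id_y: str
    loci: list[Locus]
    allele_x: list[str]
    allele_y: list[str]
    exclusions: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not (len(self.loci) == len(self.allele_x) == len(self.allele_y)):
            raise FormatError("dyad arrays have inconsistent lengths")
        if len(self.loci) == 0:
            raise NoSharedLociError(f"{self.id_x} x {self.id_y}: no shared loci")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def swapped(self) -> "DyadData":
        return DyadData(
            id_x=self.id_y,
            id_y=self.id_x,
            loci=self.loci,
            allele_x=list(self.allele_y),
            allele_y=list(self.allele_x),
            exclusions=Counter(self.exclusions),
        )


def force_site(
    site: PileupSiteCalls,
    min_qual: int = DEFAULT_MIN_QUAL,
    rng: np.random.Generator | None = None,
) -> str | None:
    """Reduce one pileup site to a single base, or ``None`` if nothing qualifies.

    One base with phred quality >= ``min_qual`` is selected uniformly at
    random. With exactly one qualifying call the choice is deterministic and
    consumes no randomness (the overwhelmingly common case at <0.1X depth).
    """
    qualifying = [b for b, q in zip(site.bases, site.quals) if q >= min_qual]
    if not qualifying:
        return None
    if len(qualifying) == 1:
        return qualifying[0]
    if rng is None:
        raise ValueError(f"site {site.locus_id}: multiple qualifying calls but no rng supplied")
    return qualifying[int(rng.integers(len(qualifying)))]


def force_dataset(
    sites: Sequence[PileupSiteCalls],
    sample_id: str,
    min_qual: int = DEFAULT_MIN_QUAL,
    seed: int = 0,
) -> HaploidGenotypes:
    """Force every pileup site of one individual to a single allele.

    Each site draws from a substream keyed by its locus id, so the result is
    independent of site order and any site can be replayed in isolation with
    :func:`force_site` and the same substream.
    """
    seen: set[str] = set()
    alleles: dict[str, str] = {}
    dropped = 0
    for site in sites:
        if site.locus_id in seen:
            raise FormatError(f"duplicate locus id {site.locus_id!r} in pileup")
        seen.add(site.locus_id)
        rng = substream(seed, "force_site", site.locus_id)
        allele = force_site(site, min_qual=min_qual, rng=rng)
        if allele is None:
            dropped += 1
        else:
            alleles[site.locus_id] = allele
    return HaploidGenotypes(sample_id=sample_id, alleles=alleles, n_dropped=dropped)


def force_diploid(
    g: DiploidGenotypes,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
) -> HaploidGenotypes:
    """Randomly drop one allele per diploid locus ("forced homozygote").

    Homozygous input returns its allele deterministically (no randomness
    consumed); heterozygous input keeps either allele with probability 1/2;
    missing calls are dropped and counted. Passing ``seed`` uses a
    per-locus substream (order-independent); passing ``rng`` draws
    sequentially in locus order. Forcing an already-haploid (duplicated)
    genotype is the identity.
    """
    if (rng is None) == (seed is None):
        raise ValueError("supply exactly one of rng or seed")
    alleles: dict[str, str] = {}
    dropped = 0
    for lid, (a, b) in g.calls.items():
        if a == MISSING or b == MISSING:
            dropped += 1
            continue
        if a == b:
            alleles[lid] = a
            continue
        if seed is not None:
            r = substream(seed, "force_diploid", g.sample_id, lid)
            pick = int(r.integers(2))
        else:
            pick = int(rng.integers(2))  # type: ignore[union-attr]
        alleles[lid] = (a, b)[pick]
    return HaploidGenotypes(sample_id=g.sample_id, alleles=alleles, n_dropped=dropped)


def intersect_dyad(
    gx: HaploidGenotypes,
    gy: HaploidGenotypes,
    freqs: AlleleFrequencyTable,
) -> DyadData:
    """Build the shared-locus table for a pair of forced individuals.

    Keeps loci called in both individuals, present in ``freqs`` with freq1
    strictly inside (0, 1), and whose two observed alleles both belong to the
    locus allele pair. Exclusion reasons are counted under the keys
    ``no_frequency``, ``monomorphic`` and ``allele_mismatch``. Symmetric up
    to swapping the (x, y) labels.
    """
    if not gx.alleles or not gy.alleles:
        raise NoSharedLociError(f"{gx.sample_id} x {gy.sample_id}: an individual has no calls")
    shared = set(gx.alleles) & set(gy.alleles)
    exclusions: Counter = Counter()
    for lid in shared:
        if lid not in freqs:
            exclusions["no_frequency"] += 1
    loci: list[Locus] = []
    ax: list[str] = []
    ay: list[str] = []
    for loc in freqs:  # panel order => stable locus order
        if loc.id not in shared:
            continue
        if loc.freq1 is None or not (0.0 < loc.freq1 < 1.0):
            exclusions["monomorphic"] += 1
            continue
        a, c = gx.alleles[loc.id], gy.alleles[loc.id]
        allowed = {loc.allele1, loc.allele2}
        if a not in allowed or c not in allowed:
            exclusions["allele_mismatch"] += 1
            continue
        loci.append(loc)
        ax.append(a)
        ay.append(c)
    if not loci:
        raise NoSharedLociError(
            f"{gx.sample_id} x {gy.sample_id}: no shared loci "
            f"({len(shared)} shared before filtering; exclusions {dict(exclusions)})"
        )
    return DyadData(
        id_x=gx.sample_id,
        id_y=gy.sample_id,
        loci=loci,
        allele_x=ax,
        allele_y=ay,
        exclusions=exclusions,
    )


def haploid_to_dataset(
    genotypes: Sequence[HaploidGenotypes],
    loci: Sequence[Locus],
) -> GenotypeDataset:
    """Assemble forced individuals into a dataset with duplicated alleles.

    Every called locus is written as a homozygous diploid call (``X X``);
    uncalled loci become missing (``0 0``).
    """
    calls = [
        [
            (g.alleles.get(loc.id, MISSING), g.alleles.get(loc.id, MISSING))
            for loc in loci
        ]
        for g in genotypes
    ]
    return GenotypeDataset(
        sample_ids=[g.sample_id for g in genotypes],
        loci=list(loci),
        calls=calls,
    )


def dataset_to_diploid(ds: GenotypeDataset, sample_id: str) -> DiploidGenotypes:
    """Extract one individual's diploid genotypes from a .ped/.map dataset."""
    return DiploidGenotypes(sample_id=sample_id, calls=ds.sample_calls(sample_id))
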