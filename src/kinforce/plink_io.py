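"""Text-format input/output: PLINK .ped/.map, .frq tables and pileup calls.

The dialects are the PLINK text conventions: whitespace-separated fields,
six mandatory leading .ped columns (family, individual, father, mother, sex,
phenotype), two allele columns per mapped locus, ``0`` as the missing-allele
code. The .frq dialect is PLINK's CHR/SNP/A1/A2/MAF[/NCHROBS] with MAF read
as the frequency of allele A1. Pileup calls use a bespoke three-column TSV:
locus id, comma-joined base calls, comma-joined phred qualities.

Alleles are single characters from {A,C,G,T}; indels are out of scope. All
positions are 1-based as in .map files. No strand flipping is ever applied:
calls whose alleles do not match a locus are excluded downstream and
counted, never complemented or recoded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import FormatError

__all__ = [
    "MISSING",
    "VALID_ALLELES",
    "Locus",
    "AlleleFrequencyTable",
    "GenotypeDataset",
    "PileupSiteCalls",
    "read_dataset",
    "write_dataset",
    "read_frq",
    "write_frq",
    "read_pileup_calls",
    "write_pileup_calls",
]

MISSING = "0"
VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP with optional reference-population frequency.

    ``freq1`` is the frequency of ``allele1`` in the reference population;
    the frequency of ``allele2`` is 1 - freq1. Loci parsed from a .map file
    carry no frequency (``freq1 is None``) until joined with a .frq table.
    """

    id: str
    chrom: str
    pos: int
    allele1: str | None = None
    allele2: str | None = None
    freq1: float | None = None

    def __post_init__(self) -> None:
        if self.allele1 is not None or self.allele2 is not None:
            for a in (self.allele1, self.allele2):
                if a not in VALID_ALLELES:
                    raise FormatError(f"locus {self.id}: allele {a!r} not one of A,C,G,T")
            if self.allele1 == self.allele2:
                raise FormatError(f"locus {self.id}: alleles must differ")
        if self.freq1 is not None and not (0.0 <= self.freq1 <= 1.0):
            raise FormatError(f"locus {self.id}: freq1={self.freq1} outside [0, 1]")
        if self.pos < 0:
            raise FormatError(f"locus {self.id}: negative position")

    @property
    def freq2(self) -> float | None:
        return None if self.freq1 is None else 1.0 - self.freq1

    def freq_of(self, allele: str) -> float:
        """Frequency of a specific carried allele (the estimator's p term)."""
        if self.freq1 is None:
            raise FormatError(f"locus {self.id} has no frequency attached")
        if allele == self.allele1:
            return self.freq1
        if allele == self.allele2:
            return 1.0 - self.freq1
        raise FormatError(f"locus {self.id}: allele {allele!r} not in ({self.allele1},{self.allele2})")


class AlleleFrequencyTable:
    """Ordered collection of loci with a lookup index by SNP id.

    Iteration order is the input-file order and is stable; ids are unique.
    """

    def __init__(self, loci: Iterable[Locus]):
        self.loci: list[Locus] = list(loci)
        self._index: dict[str, Locus] = {}
        for loc in self.loci:
            if loc.id in self._index:
                raise FormatError(f"duplicate locus id {loc.id!r}")
            self._index[loc.id] = loc

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index

    def __getitem__(self, locus_id: str) -> Locus:
        return self._index[locus_id]

    def get(self, locus_id: str) -> Locus | None:
        return self._index.get(locus_id)

    @property
    def ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def subset(self, locus_ids: Iterable[str]) -> "AlleleFrequencyTable":
        """Table restricted to ``locus_ids``, preserving this table's order."""
        wanted = set(locus_ids)
        return AlleleFrequencyTable(loc for loc in self.loci if loc.id in wanted)


@dataclass
class GenotypeDataset:
    """Diploid calls for a cohort: sample_ids x loci, one allele pair per cell.

    ``calls[i][j]`` is the (allele, allele) pair of sample i at locus j, with
    ``"0"`` as the missing code in either slot. ``metadata`` preserves the six
    leading .ped columns per sample as opaque strings.
    """

    sample_ids: list[str]
    loci: list[Locus]
    calls: list[list[tuple[str, str]]]
    metadata: dict[str, tuple[str, str, str, str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.sample_ids):
            raise FormatError("calls row count does not match sample count")
        for sid, row in zip(self.sample_ids, self.calls):
            if len(row) != len(self.loci):
                raise FormatError(f"sample {sid}: {len(row)} calls for {len(self.loci)} loci")
        for sid in self.sample_ids:
            self.metadata.setdefault(sid, (sid, sid, "0", "0", "0", "-9"))

    def sample_calls(self, sample_id: str) -> dict[str, tuple[str, str]]:
        """Mapping locus id -> diploid call for one sample (file locus order)."""
        i = self.sample_ids.index(sample_id)
        return {loc.id: call for loc, call in zip(self.loci, self.calls[i])}


@dataclass(frozen=True)
class PileupSiteCalls:
    """Per-site read-level calls: parallel base and phred-quality lists."""

    locus_id: str
    bases: tuple[str, ...]
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"site {self.locus_id}: {len(self.bases)} bases but {len(self.quals)} quals"
            )
        for q in self.quals:
            if not (0 <= q <= 93):
                raise FormatError(f"site {self.locus_id}: phred quality {q} outside [0, 93]")

    @property
    def depth(self) -> int:
        return len(self.bases)


# ---------------------------------------------------------------------------
# .ped / .map


def _read_map(map_path: str | Path) -> list[Locus]:
    loci: list[Locus] = []
    seen: set[str] = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{map_path}: line {lineno}: expected 4 columns, got {len(fields)}")
            chrom, snp_id, _cm, pos = fields[0], fields[1], fields[2], fields[3]
            if snp_id in seen:
                raise FormatError(f"{map_path}: line {lineno}: duplicate locus id {snp_id!r}")
            seen.add(snp_id)
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise FormatError(f"{map_path}: line {lineno}: non-integer position {pos!r}") from exc
            loci.append(Locus(id=snp_id, chrom=chrom, pos=pos_i))
    return loci


def read_dataset(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a text-PLINK .ped/.map pair.

    Loci come back in .map order; ``0`` alleles are the missing code; the six
    leading .ped columns are preserved as opaque metadata. A .ped row whose
    field count does not match the .map, or a duplicate individual id, is
    rejected with the offending row number.
    """
    loci = _read_map(map_path)
    n_loci = len(loci)
    sample_ids: list[str] = []
    calls: list[list[tuple[str, str]]] = []
    metadata: dict[str, tuple[str, str, str, str, str, str]] = {}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            expected = 6 + 2 * n_loci
            if len(fields) != expected:
                raise FormatError(
                    f"{ped_path}: row {lineno}: expected {expected} fields "
                    f"(6 + 2 x {n_loci} loci), got {len(fields)}"
                )
            meta = tuple(fields[:6])
            sid = meta[1]
            if sid in metadata:
                raise FormatError(f"{ped_path}: row {lineno}: duplicate sample id {sid!r}")
            row = [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_loci)]
            sample_ids.append(sid)
            calls.append(row)
            metadata[sid] = meta  # type: ignore[assignment]
    return GenotypeDataset(sample_ids=sample_ids, loci=loci, calls=calls, metadata=metadata)


def write_dataset(ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a dataset back to .ped/.map; inverse of :func:`read_dataset`.

    Forced-homozygote individuals appear with their single allele duplicated
    in both columns, which is exactly how they are stored.
    """
    with open(map_path, "w") as fh:
        for loc in ds.loci:
            fh.write(f"{loc.chrom}\t{loc.id}\t0\t{loc.pos}\n")
    with open(ped_path, "w") as fh:
        for sid, row in zip(ds.sample_ids, ds.calls):
            meta = ds.metadata[sid]
            cells = list(meta)
            for a, b in row:
                cells.append(a)
                cells.append(b)
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# .frq


def read_frq(frq_path: str | Path) -> AlleleFrequencyTable:
    """Read a PLINK .frq table; MAF is taken as the frequency of allele A1."""
    with open(frq_path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{frq_path}: empty file")
    header = text.lstrip().splitlines()[0].split()
    required = ["CHR", "SNP", "A1", "A2", "MAF"]
    if header[: len(required)] != required and not set(required).issubset(header):
        raise FormatError(f"{frq_path}: missing header (need columns {' '.join(required)})")
    df = pd.read_csv(io.StringIO(text), sep=r"\s+")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{frq_path}: missing column {col}")
    maf = pd.to_numeric(df["MAF"], errors="coerce")
    if maf.isna().any():
        bad = df.loc[maf.isna(), "SNP"].iloc[0]
        raise FormatError(f"{frq_path}: non-numeric MAF at SNP {bad}")
    out_of_range = (maf < 0.0) | (maf > 1.0)
    if out_of_range.any():
        bad = df.loc[out_of_range, "SNP"].iloc[0]
        raise FormatError(f"{frq_path}: MAF outside [0, 1] at SNP {bad}")
    loci = [
        Locus(
            id=str(row.SNP),
            chrom=str(row.CHR),
            pos=int(getattr(row, "POS", 0)),
            allele1=str(row.A1),
            allele2=str(row.A2),
            freq1=float(m),
        )
        for row, m in zip(df.itertuples(index=False), maf)
    ]
    return AlleleFrequencyTable(loci)


def write_frq(table: AlleleFrequencyTable, frq_path: str | Path) -> None:
    """Write a .frq table readable by :func:`read_frq` (fixed 6-decimal MAF)."""
    with open(frq_path, "w") as fh:
        fh.write("CHR\tSNP\tA1\tA2\tMAF\tNCHROBS\n")
        for loc in table:
            if loc.freq1 is None or loc.allele1 is None:
                raise FormatError(f"locus {loc.id}: cannot write without alleles and frequency")
            fh.write(f"{loc.chrom}\t{loc.id}\t{loc.allele1}\t{loc.allele2}\t{loc.freq1:.6f}\t0\n")


# ---------------------------------------------------------------------------
# pileup TSV


def read_pileup_calls(path: str | Path) -> list[PileupSiteCalls]:
    """Read the 3-column pileup TSV: locus id, bases, quals (comma-joined)."""
    sites: list[PileupSiteCalls] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns, got {len(fields)}")
            lid, bases_s, quals_s = fields
            bases = tuple(b for b in bases_s.split(",") if b)
            try:
                quals = tuple(int(q) for q in quals_s.split(",") if q)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer quality") from exc
            if len(bases) != len(quals):
                raise FormatError(
                    f"{path}: line {lineno}: site {lid}: "
                    f"{len(bases)} bases but {len(quals)} qualities"
                )
            sites.append(PileupSiteCalls(locus_id=lid, bases=bases, quals=quals))
    return sites


def write_pileup_calls(sites: Sequence[PileupSiteCalls], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.locus_id}\t{','.join(s.bases)}\t{','.join(str(q) for q in s.quals)}\n")
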