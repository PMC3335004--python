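"""Promoter reference regions, TSS-relative CpG numbering, and in-silico bisulfite chemistry.

A :class:`ReferenceRegion` is a promoter window on the sense strand, anchored
to 1-based coordinates of its source record and to a transcription start site
(TSS).  CpG dinucleotides are enumerated and given signed ordinal numbers
(…,-2,-1,+1,+2,…; never 0): negative ordinals count the sites upstream of the
TSS, positive ordinals those at or downstream of it.  A nucleotide boundary
relative to the TSS (default -48 nt) partitions the census into a 5' block
and a 3' block — the two blocks behave very differently as tumour markers in
liver, which is the whole point of a region-resolved analysis.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine is protected.  The in-silico
conversion here applies that rule per strand: CpG cytosines survive iff the
corresponding strand of the molecule is methylated at that site, and every
non-CpG cytosine converts with a configurable efficiency.  The fraction of
non-CpG cytosines actually converted is the standard QC statistic for
incomplete conversion.
"""

from __future__ import annotations

import enum
import random
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Region",
    "Strand",
    "ReferenceRegion",
    "CpGSite",
    "RegionPartition",
    "CpGCensus",
    "read_region",
    "enumerate_cpg_sites",
    "partition_sites",
    "annotate_regions",
    "full_state",
    "bisulfite_read_sense",
    "bisulfite_read_antisense",
    "non_cpg_conversion_rate",
    "census_table",
    "write_census_tsv",
    "read_census_tsv",
    "synthetic_promoter",
    "fetch_genbank_region",
    "DEFAULT_BOUNDARY_NT",
]

DEFAULT_BOUNDARY_NT = -48

_VALID_BASES = frozenset("ACGT")


class Region(str, enum.Enum):
    """Promoter block relative to the TSS-anchored nucleotide boundary."""

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


class Strand(str, enum.Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"


@dataclass(frozen=True)
class ReferenceRegion:
    """A promoter window on the sense strand, in 1-based source coordinates.

    Parameters
    ----------
    name : str
        Free-text label (e.g. the source accession).
    sequence : str
        Upper-case sense-strand DNA, 5'->3'.  Lower case input is upcased.
    start_offset : int
        1-based source coordinate of the first base of ``sequence``.
    tss_position : int
        1-based source coordinate of the transcription start site.
    """

    name: str
    sequence: str
    start_offset: int
    tss_position: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError("reference sequence must be non-empty")
        for i, ch in enumerate(seq):
            if ch not in _VALID_BASES:
                raise ValueError(
                    f"invalid base {ch!r} at position {i + 1} of region {self.name!r}"
                )
        # TSS must lie within the window or immediately adjacent to it.
        if not (self.start_offset - 1 <= self.tss_position <= self.end_offset + 1):
            raise ValueError(
                f"tss_position {self.tss_position} not within or adjacent to "
                f"[{self.start_offset}, {self.end_offset}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end_offset(self) -> int:
        """1-based source coordinate of the last base."""
        return self.start_offset + len(self.sequence) - 1

    @property
    def antisense_sequence(self) -> str:
        """Antisense strand in its own 5'->3' orientation (reverse complement)."""
        return str(Seq(self.sequence).reverse_complement())

    def index(self, c_position: int) -> int:
        """0-based index into ``sequence`` of a 1-based source coordinate."""
        if not (self.start_offset <= c_position <= self.end_offset):
            raise ValueError(f"coordinate {c_position} outside region")
        return c_position - self.start_offset


@dataclass(frozen=True)
class CpGSite:
    """One CpG dinucleotide, identified by its signed ordinal site number.

    ``c_position`` is the 1-based source coordinate of the sense-strand C;
    the G follows immediately.  ``region`` is filled in once a partition has
    been applied.
    """

    site_number: int
    c_position: int
    region: Region | None = None

    def tss_offset(self, tss_position: int) -> int:
        return self.c_position - tss_position


@dataclass(frozen=True)
class RegionPartition:
    """The 5'/3' split of a CpG census at a TSS-relative nucleotide boundary."""

    boundary_nt: int
    five_prime_sites: tuple[int, ...]
    three_prime_sites: tuple[int, ...]

    def region_of(self, site_number: int) -> Region:
        if site_number in self.five_prime_sites:
            return Region.FIVE_PRIME
        if site_number in self.three_prime_sites:
            return Region.THREE_PRIME
        raise KeyError(f"site {site_number} not in partition")


def read_region(
    fasta_path: str | Path,
    start_offset: int,
    tss_position: int,
    name: str | None = None,
) -> ReferenceRegion:
    """Load a single-record FASTA file as a :class:`ReferenceRegion`.

    Raises ``ValueError`` on multi-record files or non-ACGT characters (the
    error names the offending 1-based position).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record in {fasta_path}, found {len(records)}"
        )
    rec = records[0]
    return ReferenceRegion(
        name=name or rec.id,
        sequence=str(rec.seq),
        start_offset=start_offset,
        tss_position=tss_position,
    )


def enumerate_cpg_sites(region: ReferenceRegion) -> list[CpGSite]:
    """Enumerate CpG dinucleotides and number them relative to the TSS.

    Sites whose C precedes the TSS get negative ordinals ending at -1; sites
    at or after the TSS get +1, +2, …  Zero is never used.  Numbering is
    ordinal over detected sites, not a base-pair distance.
    """
    seq = region.sequence
    positions = [
        region.start_offset + i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"
    ]
    pre = [p for p in positions if p < region.tss_position]
    post = [p for p in positions if p >= region.tss_position]
    sites = [
        CpGSite(site_number=-len(pre) + k, c_position=p) for k, p in enumerate(pre)
    ]
    sites.extend(
        CpGSite(site_number=k + 1, c_position=p) for k, p in enumerate(post)
    )
    return sites


def partition_sites(
    sites: Sequence[CpGSite],
    region: ReferenceRegion,
    boundary_nt: int = DEFAULT_BOUNDARY_NT,
) -> RegionPartition:
    """Split a census at ``tss_position + boundary_nt``.

    A site is 5' iff its C lies strictly upstream of the boundary coordinate.
    The boundary must fall within the region (its 5' edge is allowed, in
    which case every site is 3').
    """
    coord = region.tss_position + boundary_nt
    if not (region.start_offset <= coord <= region.end_offset + 1):
        raise ValueError(
            f"boundary {boundary_nt} (coordinate {coord}) outside region "
            f"[{region.start_offset}, {region.end_offset}]"
        )
    five = tuple(s.site_number for s in sites if s.c_position < coord)
    three = tuple(s.site_number for s in sites if s.c_position >= coord)
    return RegionPartition(boundary_nt, five, three)


def annotate_regions(
    sites: Sequence[CpGSite], partition: RegionPartition
) -> list[CpGSite]:
    """Return the census with each site's ``region`` field filled in."""
    return [replace(s, region=partition.region_of(s.site_number)) for s in sites]


@dataclass(frozen=True)
class CpGCensus:
    """An ordered, region-annotated CpG census shared by all downstream stages."""

    sites: tuple[CpGSite, ...]
    boundary_nt: int
    tss_position: int

    @classmethod
    def from_region(
        cls, region: ReferenceRegion, boundary_nt: int = DEFAULT_BOUNDARY_NT
    ) -> "CpGCensus":
        sites = enumerate_cpg_sites(region)
        part = partition_sites(sites, region, boundary_nt)
        return cls(
            sites=tuple(annotate_regions(sites, part)),
            boundary_nt=boundary_nt,
            tss_position=region.tss_position,
        )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_numbers(self) -> tuple[int, ...]:
        return tuple(s.site_number for s in self.sites)

    @property
    def c_positions(self) -> tuple[int, ...]:
        return tuple(s.c_position for s in self.sites)

    def index_of(self, site_number: int) -> int:
        try:
            return self.site_numbers.index(site_number)
        except ValueError:
            raise KeyError(f"site {site_number} not in census") from None

    def region_indices(self, region: Region) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sites) if s.region == region], dtype=int
        )

    def region_site_numbers(self, region: Region) -> tuple[int, ...]:
        return tuple(s.site_number for s in self.sites if s.region == region)

    @property
    def partition(self) -> RegionPartition:
        return RegionPartition(
            self.boundary_nt,
            self.region_site_numbers(Region.FIVE_PRIME),
            self.region_site_numbers(Region.THREE_PRIME),
        )


# ---------------------------------------------------------------------------
# methylation state and bisulfite conversion
# ---------------------------------------------------------------------------

#: Per-molecule methylation state: site_number -> (sense methylated, antisense methylated)
MethylationState = Mapping[int, tuple[bool, bool]]


def full_state(
    sites: Iterable[CpGSite | int], sense: bool = False, antisense: bool = False
) -> dict[int, tuple[bool, bool]]:
    """Uniform methylation state over a census (convenience constructor)."""
    numbers = [s.site_number if isinstance(s, CpGSite) else int(s) for s in sites]
    return {n: (sense, antisense) for n in numbers}


def _sense_cpg_indices(region: ReferenceRegion) -> dict[int, int]:
    """0-based sequence index of each CpG C on the sense strand -> site_number."""
    return {region.index(s.c_position): s.site_number for s in enumerate_cpg_sites(region)}


def _antisense_cpg_indices(region: ReferenceRegion) -> dict[int, int]:
    """0-based index of each CpG C in the antisense 5'->3' string -> site_number.

    The antisense C of a CpG pairs with the sense G, so its index in the
    reverse-complemented string is ``len - 2 - sense_index``.
    """
    L = len(region.sequence)
    return {
        L - 2 - region.index(s.c_position): s.site_number
        for s in enumerate_cpg_sites(region)
    }


def _check_state(state: MethylationState, cpg_idx: dict[int, int]) -> None:
    missing = sorted(n for n in cpg_idx.values() if n not in state)
    if missing:
        raise ValueError(f"methylation state missing census sites: {missing}")


def _convert(
    seq: str,
    cpg_idx: dict[int, int],
    methylated: dict[int, bool],
    efficiency: float,
    rng: np.random.Generator | None,
    cpg_retention: bool,
) -> str:
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError("efficiency must be in [0, 1]")
    stochastic = efficiency < 1.0
    if stochastic and rng is None:
        raise ValueError("rng required when efficiency < 1")
    chars = list(seq)
    for i, ch in enumerate(chars):
        if ch != "C":
            continue
        if i in cpg_idx:
            if methylated[cpg_idx[i]]:
                continue  # 5mC is protected from deamination
            if cpg_retention and stochastic and rng.random() >= efficiency:
                continue  # inappropriate retention at an unmethylated CpG
            chars[i] = "T"
        else:
            if not stochastic or rng.random() < efficiency:
                chars[i] = "T"
    return "".join(chars)


def bisulfite_read_sense(
    region: ReferenceRegion,
    state: MethylationState,
    efficiency: float = 1.0,
    rng: np.random.Generator | None = None,
    cpg_retention: bool = False,
) -> str:
    """In-silico bisulfite conversion of the sense strand.

    CpG cytosines whose sense strand is methylated are preserved; all other
    cytosines convert to T, each with probability ``efficiency`` (non-CpG
    cytosines only, unless ``cpg_retention`` also subjects unmethylated CpG
    cytosines to incomplete conversion).  Conversion is deterministic at
    efficiency 1.0.
    """
    cpg_idx = _sense_cpg_indices(region)
    _check_state(state, cpg_idx)
    meth = {n: bool(state[n][0]) for n in cpg_idx.values()}
    return _convert(region.sequence, cpg_idx, meth, efficiency, rng, cpg_retention)


def bisulfite_read_antisense(
    region: ReferenceRegion,
    state: MethylationState,
    efficiency: float = 1.0,
    rng: np.random.Generator | None = None,
    cpg_retention: bool = False,
) -> str:
    """In-silico bisulfite conversion of the antisense strand (5'->3')."""
    cpg_idx = _antisense_cpg_indices(region)
    _check_state(state, cpg_idx)
    meth = {n: bool(state[n][1]) for n in cpg_idx.values()}
    return _convert(
        region.antisense_sequence, cpg_idx, meth, efficiency, rng, cpg_retention
    )


def non_cpg_conversion_rate(
    region: ReferenceRegion, read: str, strand: Strand = Strand.SENSE
) -> float:
    """Fraction of non-CpG reference cytosines read as thymine.

    This is the conversion-QC statistic: CpG cytosines are excluded from both
    numerator and denominator because their conversion depends on methylation.
    A region with zero non-CpG cytosines on the requested strand has an
    undefined rate; it is reported as 1.0 (QC pass) with a warning.
    """
    if strand == Strand.SENSE:
        ref = region.sequence
        cpg = set(_sense_cpg_indices(region))
    else:
        ref = region.antisense_sequence
        cpg = set(_antisense_cpg_indices(region))
    if len(read) != len(ref):
        raise ValueError(
            f"read length {len(read)} != reference length {len(ref)}"
        )
    read = read.upper()
    denom = 0
    num = 0
    for i, ch in enumerate(ref):
        if ch != "C" or i in cpg:
            continue
        denom += 1
        if read[i] == "T":
            num += 1
    if denom == 0:
        warnings.warn(
            "no non-CpG cytosines on this strand; conversion rate undefined, "
            "reporting QC pass",
            stacklevel=2,
        )
        return 1.0
    return num / denom


# ---------------------------------------------------------------------------
# census export / import
# ---------------------------------------------------------------------------


def census_table(census: CpGCensus) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_number": list(census.site_numbers),
            "c_position": list(census.c_positions),
            "tss_offset": [s.tss_offset(census.tss_position) for s in census.sites],
            "region": [s.region.value if s.region else "" for s in census.sites],
        }
    )


def write_census_tsv(census: CpGCensus, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# boundary_nt={census.boundary_nt}\ttss_position={census.tss_position}\n")
        census_table(census).to_csv(fh, sep="\t", index=False)


def read_census_tsv(path: str | Path) -> CpGCensus:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split("\t"))
        df = pd.read_csv(fh, sep="\t")
    sites = tuple(
        CpGSite(
            site_number=int(r.site_number),
            c_position=int(r.c_position),
            region=Region(r.region),
        )
        for r in df.itertuples()
    )
    return CpGCensus(
        sites=sites,
        boundary_nt=int(meta["boundary_nt"]),
        tss_position=int(meta["tss_position"]),
    )


# ---------------------------------------------------------------------------
# bundled synthetic promoter and optional GenBank fetch
# ---------------------------------------------------------------------------

_SYN_START = 999
_SYN_TSS = 1354
_SYN_CORE_END = 1387
_SYN_EXT_END = 1420

# TSS-relative offsets of the sense-strand C of each designed CpG.
_SYN_FIVE_OFFSETS = tuple(range(-315, -54, 13))  # 21 sites upstream of -48
_SYN_MID_OFFSETS = (-47, -41, -35, -29, -23, -17, -9)  # 7 sites in (-48, TSS)
_SYN_POST_OFFSETS = (2, 10, 18, 26)  # 4 sites at/after the TSS
_SYN_EXT_OFFSETS = (40, 48, 56)  # 3 sites past the core window (+5..+7)


def synthetic_promoter(include_extension: bool = True) -> ReferenceRegion:
    """Deterministic synthetic promoter mirroring the GSTP1 promoter layout.

    The sequence is a synthetic stand-in, not genomic DNA: it is built so that
    the core window (source coordinates 999-1387, TSS at 1354) contains
    exactly 32 CpG sites numbered -28..+4, of which 21 lie upstream of the
    -48 nt boundary and 11 at or downstream of it — the census geometry of
    the GSTP1 promoter window this package models.  With
    ``include_extension`` the window runs on past the core 3' edge and adds
    three more CpGs (+5..+7) so that an MSP reverse primer reaching beyond
    the sequenced core can still be represented.  Background bases never form
    a CpG and include non-CpG cytosines and guanines on both strands so the
    conversion-QC statistic is well defined.
    """
    end = _SYN_EXT_END if include_extension else _SYN_CORE_END
    L = end - _SYN_START + 1
    offsets = _SYN_FIVE_OFFSETS + _SYN_MID_OFFSETS + _SYN_POST_OFFSETS
    if include_extension:
        offsets = offsets + _SYN_EXT_OFFSETS
    chars: list[str | None] = [None] * L
    for off in offsets:
        i = _SYN_TSS + off - _SYN_START
        chars[i] = "C"
        chars[i + 1] = "G"
    rng = random.Random(42)
    for i in range(L):
        if chars[i] is not None:
            continue
        prev = chars[i - 1] if i > 0 else "A"
        alphabet = "AATTCG" if prev != "C" else "AATTCC"  # never G after C
        chars[i] = rng.choice(alphabet)
    return ReferenceRegion(
        name="synthetic_promoter",
        sequence="".join(chars),  # type: ignore[arg-type]
        start_offset=_SYN_START,
        tss_position=_SYN_TSS,
    )


def fetch_genbank_region(
    accession: str = "M24485",
    start: int = 999,
    end: int = 1387,
    tss_position: int | None = None,
    email: str | None = None,
) -> ReferenceRegion:
    """Fetch a GenBank record over the network and slice a promoter window.

    Optional helper; every bundled analysis runs on :func:`synthetic_promoter`
    instead, so no test or pipeline stage requires network access.
    """
    from Bio import Entrez

    Entrez.email = email or "anonymous@example.org"
    with Entrez.efetch(
        db="nucleotide", id=accession, rettype="gb", retmode="text"
    ) as handle:
        rec = SeqIO.read(handle, "genbank")
    seq = str(rec.seq[start - 1 : end])
    return ReferenceRegion(
        name=f"{accession}:{start}-{end}",
        sequence=seq,
        start_offset=start,
        tss_position=tss_position if tss_position is not None else end,
    )
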