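"""Methylation-specific PCR (MSP / MethyLight) at the molecule level.

An MSP amplicon only forms from a template molecule whose CpG sites under
the methylation-specific primers (and, for probe chemistries, the hydrolysis
probe) are all methylated on the assayed strand.  Molecule-level positivity
is therefore the joint methylation of the covered site set, optionally
relaxed by a small per-molecule mispriming probability.

Quantification mimics aliquoting a fixed number of template copies (default
300) from abundant extract into each of two duplicate reactions, counting
the amplifiable (positive) copies, and averaging the duplicates.  A sample
is called positive when the mean copy number reaches the assay's limit of
quantification (default 10 copies), which doubles as the positivity cutoff;
readings below it are treated as not detectable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort import Molecule, Sample
from .reference import CpGCensus, Strand

__all__ = [
    "Chemistry",
    "MspAssayDef",
    "MspResult",
    "default_assays",
    "assay_covered_sites",
    "molecule_msp_positive",
    "sample_positive_mask",
    "quantify_msp",
    "call_msp",
    "DEFAULT_INPUT_COPIES",
    "DEFAULT_MSP_CUTOFF",
]

DEFAULT_INPUT_COPIES = 300
DEFAULT_MSP_CUTOFF = 10.0


class Chemistry(str, enum.Enum):
    PROBE = "probe"  # hydrolysis (TaqMan) probe joins the covered set
    INTERCALATING = "intercalating"  # dye-based: primers only


@dataclass(frozen=True)
class MspAssayDef:
    """An MSP assay defined by the CpG site numbers its oligos cover."""

    name: str
    strand: Strand
    covered_sites_forward: tuple[int, ...]
    covered_sites_reverse: tuple[int, ...]
    covered_sites_probe: tuple[int, ...] = ()
    chemistry: Chemistry = Chemistry.PROBE

    def __post_init__(self) -> None:
        if not self.covered_sites_forward or not self.covered_sites_reverse:
            raise ValueError("primer covered-site lists must be non-empty")
        has_probe = len(self.covered_sites_probe) > 0
        if has_probe and self.chemistry == Chemistry.INTERCALATING:
            raise ValueError("intercalating-dye assays have no probe sites")
        if not has_probe and self.chemistry == Chemistry.PROBE:
            raise ValueError("probe chemistry requires probe sites")

    def covered_sites(self) -> tuple[int, ...]:
        return tuple(
            sorted(
                set(self.covered_sites_forward)
                | set(self.covered_sites_probe)
                | set(self.covered_sites_reverse)
            )
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "strand": self.strand.value,
            "forward": list(self.covered_sites_forward),
            "reverse": list(self.covered_sites_reverse),
            "probe": list(self.covered_sites_probe),
            "chemistry": self.chemistry.value,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MspAssayDef":
        return cls(
            name=d["name"],
            strand=Strand(d["strand"]),
            covered_sites_forward=tuple(d["forward"]),
            covered_sites_reverse=tuple(d["reverse"]),
            covered_sites_probe=tuple(d.get("probe", ())),
            chemistry=Chemistry(d.get("chemistry", "probe")),
        )


def default_assays() -> dict[str, MspAssayDef]:
    """The two bundled sense-strand assays.

    The 5' assay is a MethyLight design whose forward primer, probe, and
    reverse primer cover sites -27..-24, -23..-19, and -11..-10 (11 sites
    jointly required).  The 3' assay is a dye-based design covering -4..-2
    and +4..+7 (7 sites); its reverse primer extends past the sequenced core
    window, which is why the bundled census carries the +5..+7 extension.
    """
    return {
        "five_prime_msp": MspAssayDef(
            name="five_prime_msp",
            strand=Strand.SENSE,
            covered_sites_forward=tuple(range(-27, -23)),
            covered_sites_probe=tuple(range(-23, -18)),
            covered_sites_reverse=(-11, -10),
            chemistry=Chemistry.PROBE,
        ),
        "three_prime_msp": MspAssayDef(
            name="three_prime_msp",
            strand=Strand.SENSE,
            covered_sites_forward=(-4, -3, -2),
            covered_sites_reverse=(4, 5, 6, 7),
            chemistry=Chemistry.INTERCALATING,
        ),
    }


def assay_covered_sites(
    assay: MspAssayDef, census: CpGCensus | None = None
) -> tuple[int, ...]:
    """Sorted union of primer and probe sites; validated against a census."""
    sites = assay.covered_sites()
    if census is not None:
        missing = [n for n in sites if n not in census.site_numbers]
        if missing:
            raise KeyError(
                f"assay {assay.name!r} covers sites absent from census: {missing}"
            )
    return sites


def molecule_msp_positive(
    molecule: Molecule | Mapping[int, tuple[bool, bool]],
    assay: MspAssayDef,
    mispriming_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> bool:
    """A molecule is MSP-positive iff every covered site is methylated on the
    assayed strand; a false negative flips with probability
    ``mispriming_rate``."""
    state = molecule.state_dict() if isinstance(molecule, Molecule) else molecule
    si = 0 if assay.strand == Strand.SENSE else 1
    try:
        positive = all(bool(state[n][si]) for n in assay.covered_sites())
    except KeyError as e:
        raise KeyError(f"molecule lacks state for covered site {e}") from None
    if not positive and mispriming_rate > 0.0:
        if rng is None:
            raise ValueError("rng required when mispriming_rate > 0")
        positive = bool(rng.random() < mispriming_rate)
    return positive


def sample_positive_mask(sample: Sample, assay: MspAssayDef) -> np.ndarray:
    """Boolean mask of MSP-positive molecules in a sample (no mispriming)."""
    idx = np.array(
        [sample.census.index_of(n) for n in assay_covered_sites(assay, sample.census)],
        dtype=int,
    )
    si = 0 if assay.strand == Strand.SENSE else 1
    return sample.states[:, idx, si].all(axis=1)


@dataclass(frozen=True)
class MspResult:
    """Copies per duplicate reaction, their mean, and the positivity call."""

    sample_id: str
    assay: str
    duplicate_copies: tuple[float, ...]
    mean_copies: float
    positive: bool


def quantify_msp(
    sample: Sample,
    assay: MspAssayDef,
    input_copies: int = DEFAULT_INPUT_COPIES,
    duplicates: int = 2,
    rng: np.random.Generator | None = None,
    mispriming_rate: float = 0.0,
    cutoff: float = DEFAULT_MSP_CUTOFF,
) -> MspResult:
    """Quantify methylated copies per reaction with duplicate averaging.

    Each duplicate draws ``input_copies`` molecules from the sample with
    replacement (aliquoting from abundant extract) and counts the
    MSP-positive ones.  Duplicates are averaged before thresholding.
    """
    if input_copies < 1:
        raise ValueError("input_copies must be >= 1")
    if duplicates < 1:
        raise ValueError("duplicates must be >= 1")
    if sample.n_molecules < 1:
        raise ValueError("sample has no molecules")
    if rng is None:
        rng = np.random.default_rng()
    mask = sample_positive_mask(sample, assay)
    copies: list[float] = []
    for _ in range(duplicates):
        picks = mask[rng.integers(0, sample.n_molecules, size=input_copies)]
        if mispriming_rate > 0.0:
            flips = rng.random(input_copies) < mispriming_rate
            picks = picks | (~picks & flips)
        copies.append(float(picks.sum()))
    mean_copies = float(np.mean(copies))
    return MspResult(
        sample_id=sample.sample_id,
        assay=assay.name,
        duplicate_copies=tuple(copies),
        mean_copies=mean_copies,
        positive=mean_copies >= cutoff,
    )


def call_msp(result: MspResult, cutoff: float = DEFAULT_MSP_CUTOFF) -> bool:
    """Positivity at the copy cutoff (inclusive: exactly 10 copies is
    positive, the assay's limit of quantification)."""
    return result.mean_copies >= cutoff
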