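"""Pooled BS-PCR Sanger sequencing simulation and three-level methylation calls.

Sequencing a pooled bisulfite-PCR product reads, at each CpG, a mixture of C
(methylated templates) and T (converted templates); the relative peak height
approximates the methylated fraction of the template pool.  The simulation
reduces a sample's molecules to that per-site fraction plus truncated
Gaussian chromatogram noise.

Calls follow the chromatogram conventions of the assay: on the sense strand
a site is NONE below the detection limit (default 10%, the smallest
methylated fraction the assay reliably shows), LOW when both C and T peaks
are visible (fraction up to 50% inclusive) and HIGH when the C peak
dominates (above 50%).  The antisense read saturates: it distinguishes only
DETECTED from UNDETECTED at the same detection limit, with no LOW/HIGH
resolution.

Samples whose non-CpG cytosine conversion rate is not strictly above 95% are
dropped from all summaries (incomplete bisulfite conversion).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import Sample, TissueClass
from .reference import (
    CpGCensus,
    ReferenceRegion,
    Region,
    Strand,
    _antisense_cpg_indices,
    _sense_cpg_indices,
)

__all__ = [
    "SenseCall",
    "AntisenseCall",
    "ChromatogramProfile",
    "RegionSummary",
    "pooled_site_fractions",
    "qc_conversion",
    "call_site_sense",
    "call_site_antisense",
    "call_profile_sense",
    "call_profile_antisense",
    "sample_level_call",
    "reconstitution_experiment",
    "summarize_region",
    "compare_groups_ttest",
    "DEFAULT_DETECT_LIMIT",
    "DEFAULT_HIGH_THRESHOLD",
    "DEFAULT_QC_BOUND",
]

DEFAULT_DETECT_LIMIT = 0.10
DEFAULT_HIGH_THRESHOLD = 0.50
DEFAULT_QC_BOUND = 0.95


class SenseCall(str, enum.Enum):
    NONE = "none"
    LOW = "low"
    HIGH = "high"


class AntisenseCall(str, enum.Enum):
    UNDETECTED = "undetected"
    DETECTED = "detected"


_SENSE_ORDER = {SenseCall.NONE: 0, SenseCall.LOW: 1, SenseCall.HIGH: 2}


@dataclass
class ChromatogramProfile:
    """Per-site methylated fraction of a pooled sequencing read, one strand."""

    sample_id: str
    strand: Strand
    fractions: dict[int, float]  # site_number -> fraction of templates retaining C
    conversion_rate: float

    def __post_init__(self) -> None:
        for n, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction for site {n} out of [0, 1]: {f}")


def _strand_index(strand: Strand) -> int:
    return 0 if strand == Strand.SENSE else 1


def _non_cpg_c_count(region: ReferenceRegion, strand: Strand) -> int:
    if strand == Strand.SENSE:
        seq = region.sequence
        cpg = set(_sense_cpg_indices(region))
    else:
        seq = region.antisense_sequence
        cpg = set(_antisense_cpg_indices(region))
    return sum(1 for i, ch in enumerate(seq) if ch == "C" and i not in cpg)


def pooled_site_fractions(
    sample: Sample,
    strand: Strand,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
    efficiency: float = 1.0,
    region: ReferenceRegion | None = None,
) -> ChromatogramProfile:
    """Pool a sample's molecules into a per-site methylated-fraction profile.

    The fraction at each site is the molecule-mean methylation on the
    requested strand plus truncated Gaussian noise (sd ``noise_sd``), clipped
    to [0, 1].  The conversion rate is simulated from the bisulfite
    ``efficiency``: when a reference ``region`` is supplied, the number of
    non-CpG cytosine readouts (sites x molecules) gives the binomial
    denominator; otherwise the expected rate is reported directly.
    """
    if sample.n_molecules < 1:
        raise ValueError("sample has no molecules")
    if (noise_sd > 0 or efficiency < 1.0) and rng is None:
        raise ValueError("rng required for noisy pooling or efficiency < 1")
    si = _strand_index(strand)
    frac = sample.states[:, :, si].mean(axis=0)
    if noise_sd > 0:
        frac = frac + rng.normal(0.0, noise_sd, size=frac.shape)
    frac = np.clip(frac, 0.0, 1.0)
    if efficiency >= 1.0:
        conversion_rate = 1.0
    elif region is not None:
        n = _non_cpg_c_count(region, strand) * sample.n_molecules
        conversion_rate = 1.0 if n == 0 else float(rng.binomial(n, efficiency)) / n
    else:
        conversion_rate = efficiency
    return ChromatogramProfile(
        sample_id=sample.sample_id,
        strand=strand,
        fractions={
            n: float(f) for n, f in zip(sample.census.site_numbers, frac)
        },
        conversion_rate=conversion_rate,
    )


def qc_conversion(
    profile: ChromatogramProfile, bound: float = DEFAULT_QC_BOUND
) -> bool:
    """Conversion QC: pass iff the non-CpG conversion rate is strictly above
    the bound (a rate of exactly 95% fails)."""
    return profile.conversion_rate > bound


def _check_fraction(f: float) -> None:
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"methylated fraction out of [0, 1]: {f}")


def call_site_sense(
    meth_fraction: float,
    detect_limit: float = DEFAULT_DETECT_LIMIT,
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
) -> SenseCall:
    """Three-level sense-strand call: NONE below the detection limit, LOW up
    to the high threshold inclusive, HIGH above it.

    A fraction exactly at the detection limit is called LOW (the assay
    validation detected 10% mixtures), and exactly 50% is LOW ("50% or
    less").
    """
    _check_fraction(meth_fraction)
    if meth_fraction < detect_limit:
        return SenseCall.NONE
    if meth_fraction <= high_threshold:
        return SenseCall.LOW
    return SenseCall.HIGH


def call_site_antisense(
    meth_fraction: float, detect_limit: float = DEFAULT_DETECT_LIMIT
) -> AntisenseCall:
    """Two-level antisense call: the saturating antisense read resolves only
    detected vs undetected."""
    _check_fraction(meth_fraction)
    if meth_fraction >= detect_limit:
        return AntisenseCall.DETECTED
    return AntisenseCall.UNDETECTED


def call_profile_sense(
    profile: ChromatogramProfile,
    detect_limit: float = DEFAULT_DETECT_LIMIT,
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
) -> dict[int, SenseCall]:
    return {
        n: call_site_sense(f, detect_limit, high_threshold)
        for n, f in profile.fractions.items()
    }


def call_profile_antisense(
    profile: ChromatogramProfile, detect_limit: float = DEFAULT_DETECT_LIMIT
) -> dict[int, AntisenseCall]:
    return {
        n: call_site_antisense(f, detect_limit) for n, f in profile.fractions.items()
    }


def sample_level_call(
    profile: ChromatogramProfile,
    detect_limit: float = DEFAULT_DETECT_LIMIT,
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
):
    """Highest per-site call across the profile (the sample-level verdict of
    a validation run: a sample 'detects methylation' if any census site
    does)."""
    if profile.strand == Strand.SENSE:
        calls = call_profile_sense(profile, detect_limit, high_threshold).values()
        return max(calls, key=lambda c: _SENSE_ORDER[c])
    calls = call_profile_antisense(profile, detect_limit).values()
    return (
        AntisenseCall.DETECTED
        if AntisenseCall.DETECTED in set(calls)
        else AntisenseCall.UNDETECTED
    )


def reconstitution_experiment(
    census: CpGCensus,
    fraction_methylated: float,
    n_molecules: int = 300,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
) -> tuple[SenseCall, AntisenseCall]:
    """Simulate one reconstitution standard: a pool mixing fully methylated
    and fully unmethylated molecules at a stated ratio, read on both strands.

    Returns the sample-level (sense, antisense) verdicts.
    """
    _check_fraction(fraction_methylated)
    if rng is None:
        rng = np.random.default_rng()
    n_meth = int(round(fraction_methylated * n_molecules))
    states = np.zeros((n_molecules, census.n_sites, 2), dtype=bool)
    states[:n_meth] = True
    sample = Sample(
        sample_id=f"reconstitution_{fraction_methylated:.2f}",
        tissue_class=TissueClass.NONLIVER_NORMAL,
        states=states,
        census=census,
    )
    sense = pooled_site_fractions(sample, Strand.SENSE, noise_sd=noise_sd, rng=rng)
    anti = pooled_site_fractions(sample, Strand.ANTISENSE, noise_sd=noise_sd, rng=rng)
    return sample_level_call(sense), sample_level_call(anti)


# ---------------------------------------------------------------------------
# region summaries and group comparison
# ---------------------------------------------------------------------------


@dataclass
class RegionSummary:
    """Category percentages over site x sample units for one class and block,
    plus the mean/sd of the per-sample detected fraction (LOW + HIGH)."""

    tissue_class: str
    region: Region
    n_samples: int
    n_sites: int
    pct_none: float
    pct_low: float
    pct_high: float
    mean_detected: float
    sd_detected: float
    per_sample_detected: tuple[float, ...]


def summarize_region(
    calls_by_sample: Mapping[str, Mapping[int, SenseCall]],
    region_sites: Sequence[int],
    region: Region,
    tissue_class: str = "",
) -> RegionSummary:
    """Summarise sense-strand calls for one tissue class over one block.

    Percentages are computed over all site x sample units; the detected
    fraction of each sample is the share of its sites called LOW or HIGH.
    """
    if not calls_by_sample:
        raise ValueError("no samples to summarize")
    if not region_sites:
        raise ValueError("region has no sites")
    counts = {SenseCall.NONE: 0, SenseCall.LOW: 0, SenseCall.HIGH: 0}
    per_sample: list[float] = []
    for _, calls in calls_by_sample.items():
        detected = 0
        for site in region_sites:
            c = calls[site]
            counts[c] += 1
            if c != SenseCall.NONE:
                detected += 1
        per_sample.append(100.0 * detected / len(region_sites))
    total = sum(counts.values())
    arr = np.asarray(per_sample)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan")
    return RegionSummary(
        tissue_class=tissue_class,
        region=region,
        n_samples=len(calls_by_sample),
        n_sites=len(region_sites),
        pct_none=100.0 * counts[SenseCall.NONE] / total,
        pct_low=100.0 * counts[SenseCall.LOW] / total,
        pct_high=100.0 * counts[SenseCall.HIGH] / total,
        mean_detected=float(arr.mean()),
        sd_detected=sd,
        per_sample_detected=tuple(per_sample),
    )


def compare_groups_ttest(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided pooled-variance (Student's) t test on per-sample detected
    fractions.

    Degenerate convention: with zero pooled variance the test is undefined;
    equal means are reported as (0, 1) and unequal means as (+/-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    se = np.sqrt(pooled_var * (1.0 / len(a) + 1.0 / len(b)))
    t = float((a.mean() - b.mean()) / se)
    df = len(a) + len(b) - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p
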