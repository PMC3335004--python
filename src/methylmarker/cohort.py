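"""Synthetic tissue cohorts with class-conditional, molecule-level methylation.

The generator realises a two-level mixture per promoter block: a molecule
first either carries methylation in a block (probability ``f_meth``) or not;
a carrier molecule is then methylated at each CpG of the block independently
with probability ``p_site``, symmetrically on both strands except for rare
hemimethylation (``sym_error``).  The two levels make molecule-level
co-methylation density — what an MSP assay actually interrogates — tunable
independently of the per-site marginal ``f_meth * p_site`` that pooled
sequencing sees.

Default parameters are synthetic choices.  Only their ordering structure is
anchored in the biology being emulated: the 3' block of the promoter is
methylated in every adult liver-lineage tissue but in neither fetal liver
nor non-liver tissues (liver-specific methylation), while the 5' block is
densely methylated in HCC, intermediately in adjacent non-tumour liver
(field effect), and essentially absent from normal, hepatitis, and cirrhotic
liver.  Serum AFP for HCC-bearing subjects is drawn from a heavy-tailed
log-normal calibrated so that about 54% of cases fall below the 20 ng/mL
AFP-negativity threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .reference import CpGCensus, Region, synthetic_promoter

__all__ = [
    "TissueClass",
    "ADULT_LIVER_LINEAGE",
    "NONLIVER_ORGANS",
    "RegionParams",
    "MethylationModel",
    "default_model",
    "Molecule",
    "Sample",
    "Cohort",
    "CohortSpec",
    "default_cohort_spec",
    "generate_molecule",
    "generate_sample",
    "generate_cohort",
    "sample_afp",
    "write_cohort",
    "read_cohort",
    "AFP_LOG_MU",
    "AFP_LOG_SIGMA",
    "AFP_NEGATIVE_THRESHOLD",
]


class TissueClass(str, enum.Enum):
    NORMAL_LIVER = "normal_liver"
    FETAL_LIVER = "fetal_liver"
    NONLIVER_NORMAL = "nonliver_normal"
    HEPATITIS = "hepatitis"
    CIRRHOSIS = "cirrhosis"
    ADJACENT_NON_HCC = "adjacent_non_hcc"
    HCC = "hcc"


#: Adult liver-lineage classes: all show constitutive 3'-block methylation.
ADULT_LIVER_LINEAGE = frozenset(
    {
        TissueClass.NORMAL_LIVER,
        TissueClass.HEPATITIS,
        TissueClass.CIRRHOSIS,
        TissueClass.ADJACENT_NON_HCC,
        TissueClass.HCC,
    }
)

#: Organ labels cycled through for NONLIVER_NORMAL samples.
NONLIVER_ORGANS = (
    "pancreas",
    "pbmc",
    "lung",
    "heart",
    "colon",
    "esophagus",
    "kidney",
    "spleen",
    "stomach",
    "breast",
    "trigeminal_ganglion",
)

# Serum AFP (ng/mL) for HCC subjects: log-normal, calibrated so that
# P(AFP < 20) ~ 0.54, i.e. (ln 20 - mu)/sigma = Phi^-1(0.54).
AFP_LOG_SIGMA = 2.2
AFP_LOG_MU = 2.774777
AFP_NEGATIVE_THRESHOLD = 20.0


def _check_prob(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {x}")


@dataclass(frozen=True)
class RegionParams:
    """Per-(class, block) parameters of the two-level mixture."""

    f_meth: float  # fraction of molecules carrying methylation in the block
    p_site: float  # per-site methylation probability on a carrier molecule

    def __post_init__(self) -> None:
        _check_prob(self.f_meth, "f_meth")
        _check_prob(self.p_site, "p_site")


@dataclass
class MethylationModel:
    """Class-conditional methylation model for the synthetic cohort generator.

    Attributes
    ----------
    params : mapping (TissueClass, Region) -> RegionParams
    sym_error : float
        Probability a methylated CpG is hemimethylated (one strand cleared).
    mispriming_rate : float
        Per-molecule false MSP positivity probability (default 0).
    sample_dispersion : float or None
        Beta concentration for sample-to-sample variation of the carrier
        fraction.  ``None`` disables overdispersion; molecule-level draws
        (``generate_molecule``) always use the class-level ``f_meth``.
    """

    params: dict[tuple[TissueClass, Region], RegionParams]
    sym_error: float = 0.05
    mispriming_rate: float = 0.0
    sample_dispersion: float | None = 8.0

    def __post_init__(self) -> None:
        _check_prob(self.sym_error, "sym_error")
        _check_prob(self.mispriming_rate, "mispriming_rate")
        if self.sample_dispersion is not None and self.sample_dispersion <= 0:
            raise ValueError("sample_dispersion must be positive or None")

    def region_params(self, tissue_class: TissueClass, region: Region) -> RegionParams:
        return self.params[(tissue_class, region)]

    def expected_marginal(self, tissue_class: TissueClass, region: Region) -> float:
        """Expected per-site, per-strand methylated fraction."""
        rp = self.region_params(tissue_class, region)
        return rp.f_meth * rp.p_site * (1.0 - self.sym_error / 2.0)

    def expected_full_coverage_rate(
        self, tissue_class: TissueClass, region: Region, n_sites: int
    ) -> float:
        """Expected fraction of molecules methylated at all ``n_sites`` sites
        of a block on one strand (what an MSP amplicon requires)."""
        rp = self.region_params(tissue_class, region)
        per_site = rp.p_site * (1.0 - self.sym_error / 2.0)
        return rp.f_meth * per_site**n_sites

    def to_dict(self) -> dict:
        return {
            "sym_error": self.sym_error,
            "mispriming_rate": self.mispriming_rate,
            "sample_dispersion": self.sample_dispersion,
            "params": {
                cls_.value: {
                    reg.value: {
                        "f_meth": self.params[(cls_, reg)].f_meth,
                        "p_site": self.params[(cls_, reg)].p_site,
                    }
                    for reg in Region
                    if (cls_, reg) in self.params
                }
                for cls_ in TissueClass
                if any((cls_, reg) in self.params for reg in Region)
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MethylationModel":
        params = {
            (TissueClass(c), Region(r)): RegionParams(**rp)
            for c, regs in d["params"].items()
            for r, rp in regs.items()
        }
        return cls(
            params=params,
            sym_error=d.get("sym_error", 0.05),
            mispriming_rate=d.get("mispriming_rate", 0.0),
            sample_dispersion=d.get("sample_dispersion", 8.0),
        )


def default_model() -> MethylationModel:
    """Documented default model.

    All numeric values are synthetic; the constraints they encode are: 3'
    carrier fractions high in adult liver lineage and zero in fetal liver and
    non-liver tissue; 5' methylation density ordered
    HCC > adjacent non-HCC >> normal/hepatitis/cirrhosis ~ 0.
    """
    five = {
        TissueClass.NORMAL_LIVER: RegionParams(0.03, 0.30),
        TissueClass.HEPATITIS: RegionParams(0.03, 0.30),
        TissueClass.CIRRHOSIS: RegionParams(0.04, 0.30),
        TissueClass.ADJACENT_NON_HCC: RegionParams(0.25, 0.60),
        TissueClass.HCC: RegionParams(0.45, 0.80),
        TissueClass.FETAL_LIVER: RegionParams(0.0, 0.0),
        TissueClass.NONLIVER_NORMAL: RegionParams(0.0, 0.0),
    }
    three = {
        TissueClass.NORMAL_LIVER: RegionParams(0.80, 0.80),
        TissueClass.HEPATITIS: RegionParams(0.45, 0.70),
        TissueClass.CIRRHOSIS: RegionParams(0.20, 0.70),
        TissueClass.ADJACENT_NON_HCC: RegionParams(0.50, 0.75),
        TissueClass.HCC: RegionParams(0.50, 0.85),
        TissueClass.FETAL_LIVER: RegionParams(0.0, 0.0),
        TissueClass.NONLIVER_NORMAL: RegionParams(0.0, 0.0),
    }
    params: dict[tuple[TissueClass, Region], RegionParams] = {}
    for cls_, rp in five.items():
        params[(cls_, Region.FIVE_PRIME)] = rp
    for cls_, rp in three.items():
        params[(cls_, Region.THREE_PRIME)] = rp
    return MethylationModel(params=params)


# ---------------------------------------------------------------------------
# molecules, samples, cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Molecule:
    """Dual-strand methylation state of one DNA duplex over the census.

    ``states`` has shape (n_sites, 2); column 0 is the sense strand and
    column 1 the antisense strand.
    """

    site_numbers: tuple[int, ...]
    states: np.ndarray

    def is_methylated(self, site_number: int, strand_index: int = 0) -> bool:
        return bool(self.states[self.site_numbers.index(site_number), strand_index])

    def state_dict(self) -> dict[int, tuple[bool, bool]]:
        return {
            n: (bool(self.states[i, 0]), bool(self.states[i, 1]))
            for i, n in enumerate(self.site_numbers)
        }


@dataclass
class Sample:
    sample_id: str
    tissue_class: TissueClass
    states: np.ndarray  # (n_molecules, n_sites, 2) bool
    census: CpGCensus
    afp_ng_ml: float | None = None
    organ: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.states.shape[0] < 1:
            raise ValueError("a sample must contain at least one molecule")
        if self.states.shape[1] != self.census.n_sites or self.states.shape[2] != 2:
            raise ValueError("states shape inconsistent with census")

    @property
    def n_molecules(self) -> int:
        return int(self.states.shape[0])

    def molecule(self, i: int) -> Molecule:
        return Molecule(self.census.site_numbers, self.states[i])

    def molecules(self) -> Iterator[Molecule]:
        for i in range(self.n_molecules):
            yield self.molecule(i)


@dataclass
class Cohort:
    census: CpGCensus
    samples: list[Sample]
    model: MethylationModel | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def by_class(self, tissue_class: TissueClass) -> list[Sample]:
        return [s for s in self.samples if s.tissue_class == tissue_class]


def _generate_states(
    model: MethylationModel,
    tissue_class: TissueClass,
    census: CpGCensus,
    n_molecules: int,
    rng: np.random.Generator,
    dispersion: float | None,
) -> np.ndarray:
    states = np.zeros((n_molecules, census.n_sites, 2), dtype=bool)
    for region in Region:
        idx = census.region_indices(region)
        if idx.size == 0:
            continue
        rp = model.region_params(tissue_class, region)
        f = rp.f_meth
        if dispersion is not None and 0.0 < f < 1.0:
            f = float(rng.beta(dispersion * f, dispersion * (1.0 - f)))
        carrier = rng.random(n_molecules) < f
        site_m = (rng.random((n_molecules, idx.size)) < rp.p_site) & carrier[:, None]
        duplex = np.repeat(site_m[:, :, None], 2, axis=2)
        if model.sym_error > 0.0:
            hemi = (rng.random((n_molecules, idx.size)) < model.sym_error) & site_m
            which = rng.integers(0, 2, size=(n_molecules, idx.size))
            duplex[:, :, 0] &= ~(hemi & (which == 0))
            duplex[:, :, 1] &= ~(hemi & (which == 1))
        states[:, idx, :] = duplex
    return states


def generate_molecule(
    model: MethylationModel,
    tissue_class: TissueClass,
    census: CpGCensus,
    rng: np.random.Generator,
) -> Molecule:
    """Draw one molecule from the class-conditional two-level mixture."""
    states = _generate_states(model, tissue_class, census, 1, rng, dispersion=None)
    return Molecule(census.site_numbers, states[0])


def sample_afp(
    tissue_class: TissueClass, rng: np.random.Generator
) -> float:
    """Draw a serum AFP value (ng/mL) for an HCC-bearing subject."""
    if tissue_class != TissueClass.HCC:
        raise ValueError("AFP values are drawn for HCC samples only")
    return float(rng.lognormal(mean=AFP_LOG_MU, sigma=AFP_LOG_SIGMA))


# Clinicopathological attribute frequencies used to decorate HCC samples,
# and viral-status frequencies for hepatitis/cirrhosis samples.
_HCC_STAGE = (("1", 48), ("2", 48), ("3", 16), ("4", 4), ("unknown", 4))
_HCC_GRADE = (("1", 18), ("2", 74), ("3", 23), ("unknown", 5))
_VIRAL = {
    TissueClass.HCC: (("hbv", 63), ("hcv", 33), ("other", 24)),
    TissueClass.HEPATITIS: (("hbv", 11), ("hcv", 19), ("other", 5)),
    TissueClass.CIRRHOSIS: (("hbv", 4), ("hcv", 21), ("other", 10)),
}


def _weighted_choice(rng: np.random.Generator, table) -> str:
    labels = [t[0] for t in table]
    w = np.array([t[1] for t in table], dtype=float)
    return str(rng.choice(labels, p=w / w.sum()))


def generate_sample(
    model: MethylationModel,
    tissue_class: TissueClass,
    n_molecules: int,
    census: CpGCensus,
    rng: np.random.Generator,
    sample_id: str | None = None,
    organ: str | None = None,
) -> Sample:
    """Draw one sample: molecules plus AFP and clinicopathological attributes.

    Sample-to-sample heterogeneity of the carrier fraction is applied here
    (``model.sample_dispersion``); molecule-level draws within the sample are
    conditionally independent given the sample's carrier fraction.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    states = _generate_states(
        model, tissue_class, census, n_molecules, rng, model.sample_dispersion
    )
    afp = sample_afp(tissue_class, rng) if tissue_class == TissueClass.HCC else None
    attributes: dict[str, str] = {}
    if tissue_class == TissueClass.HCC:
        attributes["stage"] = _weighted_choice(rng, _HCC_STAGE)
        attributes["grade"] = _weighted_choice(rng, _HCC_GRADE)
    if tissue_class in _VIRAL:
        attributes["viral_status"] = _weighted_choice(rng, _VIRAL[tissue_class])
    return Sample(
        sample_id=sample_id or f"{tissue_class.value}_0",
        tissue_class=tissue_class,
        states=states,
        census=census,
        afp_ng_ml=afp,
        organ=organ,
        attributes=attributes,
    )


@dataclass
class CohortSpec:
    """Per-class sample counts, molecules per sample, and the seed."""

    class_counts: dict[TissueClass, int]
    n_molecules: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for cls_, n in self.class_counts.items():
            if n < 0:
                raise ValueError(f"negative sample count for {cls_}: {n}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Default cohort arm sizes: 120 HCC, 35 hepatitis, 35 cirrhosis."""
    return CohortSpec(
        class_counts={
            TissueClass.HCC: 120,
            TissueClass.HEPATITIS: 35,
            TissueClass.CIRRHOSIS: 35,
        },
        seed=seed,
    )


def generate_cohort(
    spec: CohortSpec,
    model: MethylationModel | None = None,
    census: CpGCensus | None = None,
) -> Cohort:
    """Generate a reproducible cohort from a spec (seeded)."""
    model = model if model is not None else default_model()
    if census is None:
        census = CpGCensus.from_region(synthetic_promoter(include_extension=True))
    rng = np.random.default_rng(spec.seed)
    samples: list[Sample] = []
    organ_cycle = 0
    for tissue_class in TissueClass:  # fixed enum order keeps generation stable
        n = spec.class_counts.get(tissue_class, 0)
        for k in range(n):
            organ = None
            if tissue_class == TissueClass.NONLIVER_NORMAL:
                organ = NONLIVER_ORGANS[organ_cycle % len(NONLIVER_ORGANS)]
                organ_cycle += 1
            samples.append(
                generate_sample(
                    model,
                    tissue_class,
                    spec.n_molecules,
                    census,
                    rng,
                    sample_id=f"{tissue_class.value}_{k + 1:03d}",
                    organ=organ,
                )
            )
    return Cohort(census=census, samples=samples, model=model, seed=spec.seed)


# ---------------------------------------------------------------------------
# cohort I/O (plain TSV + bitstring molecule matrices)
# ---------------------------------------------------------------------------


def _bits(row: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in row)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write census, sample table, molecule matrices, and model config."""
    from .reference import write_census_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    census_path = outdir / "census.tsv"
    write_census_tsv(cohort.census, census_path)

    rows = []
    for s in cohort.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "tissue_class": s.tissue_class.value,
                "organ": s.organ or "",
                "n_molecules": s.n_molecules,
                "afp_ng_ml": "" if s.afp_ng_ml is None else f"{s.afp_ng_ml:.4f}",
                "stage": s.attributes.get("stage", ""),
                "grade": s.attributes.get("grade", ""),
                "viral_status": s.attributes.get("viral_status", ""),
            }
        )
    samples_path = outdir / "samples.tsv"
    pd.DataFrame(rows).to_csv(samples_path, sep="\t", index=False)

    molecules_path = outdir / "molecules.tsv"
    with open(molecules_path, "w") as fh:
        fh.write("sample_id\tmolecule_index\tsense\tantisense\n")
        for s in cohort.samples:
            for i in range(s.n_molecules):
                fh.write(
                    f"{s.sample_id}\t{i}\t{_bits(s.states[i, :, 0])}\t"
                    f"{_bits(s.states[i, :, 1])}\n"
                )

    model_path = outdir / "model.yaml"
    if cohort.model is not None:
        with open(model_path, "w") as fh:
            yaml.safe_dump(cohort.model.to_dict(), fh, sort_keys=True)

    return {
        "census": census_path,
        "samples": samples_path,
        "molecules": molecules_path,
        "model": model_path,
    }


def read_cohort(indir: str | Path) -> Cohort:
    from .reference import read_census_tsv

    indir = Path(indir)
    census = read_census_tsv(indir / "census.tsv")
    samples_df = pd.read_csv(
        indir / "samples.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    mol_df = pd.read_csv(indir / "molecules.tsv", sep="\t", dtype=str)
    model = None
    model_path = indir / "model.yaml"
    if model_path.exists():
        with open(model_path) as fh:
            model = MethylationModel.from_dict(yaml.safe_load(fh))

    grouped = mol_df.groupby("sample_id", sort=False)
    samples: list[Sample] = []
    for row in samples_df.itertuples():
        g = grouped.get_group(row.sample_id)
        n_mol = len(g)
        states = np.zeros((n_mol, census.n_sites, 2), dtype=bool)
        for j, (sense, anti) in enumerate(zip(g["sense"], g["antisense"])):
            states[j, :, 0] = np.frombuffer(sense.encode(), dtype=np.uint8) == ord("1")
            states[j, :, 1] = np.frombuffer(anti.encode(), dtype=np.uint8) == ord("1")
        afp = float(row.afp_ng_ml) if row.afp_ng_ml else None
        attributes = {
            key: getattr(row, key)
            for key in ("stage", "grade", "viral_status")
            if getattr(row, key)
        }
        organ = row.organ or None
        samples.append(
            Sample(
                sample_id=row.sample_id,
                tissue_class=TissueClass(row.tissue_class),
                states=states,
                census=census,
                afp_ng_ml=afp,
                organ=organ,
                attributes=attributes,
            )
        )
    return Cohort(census=census, samples=samples, model=model, seed=None)
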