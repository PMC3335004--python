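"""MSP assay definitions, molecule-level positivity, and copy quantification."""

import itertools

import numpy as np
import pytest

from methylmarker.cohort import Molecule, Sample, TissueClass
from methylmarker.msp import (
    Chemistry,
    MspAssayDef,
    assay_covered_sites,
    call_msp,
    default_assays,
    molecule_msp_positive,
    quantify_msp,
    sample_positive_mask,
)
from methylmarker.reference import Strand


def molecule_with(census, methylated_sites, strand_index=0):
    states = np.zeros((census.n_sites, 2), dtype=bool)
    for n in methylated_sites:
        states[census.index_of(n), strand_index] = True
    return Molecule(census.site_numbers, states)


def sample_from_mask(census, positive_mask, assay):
    """Sample whose molecules are fully methylated (positive) or blank."""
    n = len(positive_mask)
    states = np.zeros((n, census.n_sites, 2), dtype=bool)
    states[np.asarray(positive_mask, bool)] = True
    return Sample("s", TissueClass.HCC, states, census)


class TestAssayDefs:
    def test_five_prime_covers_eleven_sites(self):
        assay = default_assays()["five_prime_msp"]
        sites = assay_covered_sites(assay)
        assert sites == tuple([-27, -26, -25, -24, -23, -22, -21, -20, -19, -11, -10])
        assert len(sites) == 11
        assert assay.chemistry == Chemistry.PROBE

    def test_three_prime_covers_seven_sites(self):
        assay = default_assays()["three_prime_msp"]
        sites = assay_covered_sites(assay)
        assert sites == (-4, -3, -2, 4, 5, 6, 7)
        assert assay.chemistry == Chemistry.INTERCALATING

    def test_minimal_assay(self):
        assay = MspAssayDef(
            "mini", Strand.SENSE, (-5,), (3,), chemistry=Chemistry.INTERCALATING
        )
        assert assay_covered_sites(assay) == (-5, 3)

    def test_probe_chemistry_requires_probe_sites(self):
        with pytest.raises(ValueError):
            MspAssayDef("bad", Strand.SENSE, (-5,), (3,), chemistry=Chemistry.PROBE)
        with pytest.raises(ValueError):
            MspAssayDef(
                "bad", Strand.SENSE, (-5,), (3,), covered_sites_probe=(1,),
                chemistry=Chemistry.INTERCALATING,
            )

    def test_site_absent_from_census_rejected(self, census):
        assay = MspAssayDef(
            "off", Strand.SENSE, (-40,), (3,), chemistry=Chemistry.INTERCALATING
        )
        with pytest.raises(KeyError, match="-40"):
            assay_covered_sites(assay, census)

    def test_three_prime_reverse_primer_needs_extended_census(self):
        from methylmarker.reference import CpGCensus, synthetic_promoter

        core = CpGCensus.from_region(synthetic_promoter(include_extension=False))
        with pytest.raises(KeyError):
            assay_covered_sites(default_assays()["three_prime_msp"], core)


class TestMoleculePositivity:
    def test_joint_methylation_required(self, census):
        assay = default_assays()["five_prime_msp"]
        full = molecule_with(census, assay_covered_sites(assay))
        assert molecule_msp_positive(full, assay)
        missing_one = molecule_with(census, assay_covered_sites(assay)[1:])
        assert not molecule_msp_positive(missing_one, assay)
        blank = molecule_with(census, [])
        assert not molecule_msp_positive(blank, assay)

    def test_positivity_is_strand_specific(self, census):
        assay = default_assays()["five_prime_msp"]
        anti_only = molecule_with(census, assay_covered_sites(assay), strand_index=1)
        assert not molecule_msp_positive(anti_only, assay)

    def test_mispriming_flips_negative(self, census, rng):
        assay = default_assays()["five_prime_msp"]
        blank = molecule_with(census, [])
        flips = sum(
            molecule_msp_positive(blank, assay, mispriming_rate=0.3, rng=rng)
            for _ in range(2000)
        )
        assert flips / 2000 == pytest.approx(0.3, abs=0.03)

    def test_monotone_in_methylation(self, census):
        """Adding methylation never turns a positive molecule negative."""
        assay = default_assays()["three_prime_msp"]
        covered = assay_covered_sites(assay)
        base = molecule_with(census, covered)
        assert molecule_msp_positive(base, assay)
        more = molecule_with(census, list(covered) + [-28, -27, 1])
        assert molecule_msp_positive(more, assay)


class TestQuantify:
    def test_no_positive_molecules(self, census):
        assay = default_assays()["five_prime_msp"]
        sample = sample_from_mask(census, [False] * 50, assay)
        res = quantify_msp(sample, assay, rng=np.random.default_rng(0))
        assert res.mean_copies == 0.0
        assert not res.positive

    def test_all_positive_molecules(self, census):
        assay = default_assays()["five_prime_msp"]
        sample = sample_from_mask(census, [True] * 50, assay)
        res = quantify_msp(sample, assay, rng=np.random.default_rng(0))
        assert res.mean_copies == 300.0
        assert res.duplicate_copies == (300.0, 300.0)
        assert res.positive

    def test_binomial_moments_at_five_percent(self, census):
        """positive fraction 0.05 -> mean copies ~ 15, per-duplicate
        sd ~ sqrt(300 * 0.05 * 0.95) ~ 3.8."""
        assay = default_assays()["five_prime_msp"]
        mask = [True] * 5 + [False] * 95
        sample = sample_from_mask(census, mask, assay)
        rng = np.random.default_rng(33)
        singles = []
        for _ in range(1000):
            res = quantify_msp(sample, assay, duplicates=1, rng=rng)
            singles.append(res.mean_copies)
        assert np.mean(singles) == pytest.approx(15.0, abs=0.5)
        assert np.std(singles) == pytest.approx(3.77, abs=0.4)

    def test_empty_and_invalid_inputs(self, census):
        assay = default_assays()["five_prime_msp"]
        sample = sample_from_mask(census, [True], assay)
        with pytest.raises(ValueError):
            quantify_msp(sample, assay, input_copies=0)
        with pytest.raises(ValueError):
            quantify_msp(sample, assay, duplicates=0)

    def test_sampling_monotonicity(self, census):
        """Methylating more molecules never lowers the positive count drawn
        under the same random aliquots."""
        assay = default_assays()["three_prime_msp"]
        few = sample_from_mask(census, [True] * 10 + [False] * 90, assay)
        more = sample_from_mask(census, [True] * 40 + [False] * 60, assay)
        r1 = quantify_msp(few, assay, rng=np.random.default_rng(5))
        r2 = quantify_msp(more, assay, rng=np.random.default_rng(5))
        assert r2.mean_copies >= r1.mean_copies


class TestCallMsp:
    @pytest.mark.parametrize("mean,expected", [(12.0, True), (9.0, False), (10.0, True)])
    def test_cutoff_inclusive_at_limit_of_quantification(self, census, mean, expected):
        from methylmarker.msp import MspResult

        res = MspResult("s", "a", (mean, mean), mean, mean >= 10)
        assert call_msp(res) is expected


class TestEnumerationOracle:
    @pytest.mark.parametrize("k,p", [(5, 0.6), (7, 0.8), (11, 0.9)])
    def test_positive_fraction_matches_exhaustive_enumeration(self, census, k, p):
        """Under independent per-site methylation with probability p the
        simulated positive-molecule fraction matches the exhaustive 2^k
        enumeration expectation (= p^k) within 3 binomial SEs."""
        from methylmarker.cohort import (
            MethylationModel,
            RegionParams,
            generate_sample,
        )
        from methylmarker.reference import Region

        sites = assay_covered_sites(default_assays()["five_prime_msp"])[:k]
        assay = MspAssayDef(
            "oracle", Strand.SENSE, sites[:1], sites[1:] or sites[:1],
            chemistry=Chemistry.INTERCALATING,
        )
        # exhaustive oracle: sum over all 2^k patterns
        expected = 0.0
        for pattern in itertools.product([0, 1], repeat=k):
            prob = np.prod([p if b else 1 - p for b in pattern])
            expected += prob * all(pattern)
        assert expected == pytest.approx(p**k, rel=1e-9)

        model = MethylationModel(
            params={(TissueClass.HCC, reg): RegionParams(1.0, p) for reg in Region},
            sym_error=0.0,
            sample_dispersion=None,
        )
        n = 20_000
        sample = generate_sample(
            model, TissueClass.HCC, n, census, np.random.default_rng(13)
        )
        observed = sample_positive_mask(sample, assay).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    def test_five_prime_needs_more_joint_sites_than_three_prime(self, census):
        """11 jointly methylated sites vs 7: under equal per-site marginals
        the 5' positivity rate is strictly below the 3' rate for p < 1."""
        from methylmarker.cohort import (
            MethylationModel,
            RegionParams,
            generate_sample,
        )
        from methylmarker.reference import Region

        assays = default_assays()
        assert len(assay_covered_sites(assays["five_prime_msp"])) == 11
        assert len(assay_covered_sites(assays["three_prime_msp"])) == 7
        model = MethylationModel(
            params={(TissueClass.HCC, reg): RegionParams(1.0, 0.8) for reg in Region},
            sym_error=0.0,
            sample_dispersion=None,
        )
        sample = generate_sample(
            model, TissueClass.HCC, 20_000, census, np.random.default_rng(21)
        )
        rate5 = sample_positive_mask(sample, assays["five_prime_msp"]).mean()
        rate3 = sample_positive_mask(sample, assays["three_prime_msp"]).mean()
        assert rate5 < rate3
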