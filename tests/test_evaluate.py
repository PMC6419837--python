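"""Sample partitioning, coverage vs. the ideal bound, frequency spectra, n-grams."""

import numpy as np
import pytest
from scipy import stats

from chemcover import chemspace as cs
from chemcover import evaluate as ev
from chemcover import idealmodel as im
from chemcover.lm import SampledSequence


def _uniform_sample(space, k, rng):
    pool = sorted(space.molecules)
    return [pool[i] for i in rng.integers(0, len(pool), size=k)]


class TestEvaluateSample:
    def test_space_itself_covers_fully(self, toy_space):
        rep = ev.evaluate_sample(sorted(toy_space.molecules), toy_space)
        assert rep.valid == rep.canonical_as_generated == rep.in_space == toy_space.n
        assert rep.coverage_fraction == 1.0
        assert rep.out_of_space == 0

    def test_partition_is_complete(self, toy_space):
        sample = ["CCO", "C1CC", "QXZ", "CCCCCCCC", "OCC", "C"]
        rep = ev.evaluate_sample(sample, toy_space)
        assert rep.valid + rep.invalid == rep.total == 6
        assert rep.in_space + rep.out_of_space == rep.valid
        assert rep.invalid == 2  # unclosed ring and garbage

    def test_canonical_as_generated_string_equality(self, toy_space):
        rep = ev.evaluate_sample(["CCO", "OCC"], toy_space)
        assert rep.valid == 2
        assert rep.canonical_as_generated == 1  # only "CCO" was written canonically
        assert rep.unique_in_space == 1

    def test_truncated_records_count_invalid(self, toy_space):
        sample = [SampledSequence("CCO", 1.0, truncated=True), "CCO"]
        rep = ev.evaluate_sample(sample, toy_space)
        assert rep.invalid == 1 and rep.valid == 1

    def test_uniform_sampler_matches_ideal_fraction(self, toy_space):
        """k=500 uniform draws from n=200 cover ~1-(1-1/200)^500 of the space."""
        n, k, trials = 200, 500, 20
        pool = sorted(toy_space.molecules)[:n]
        sub = cs.ReferenceSpace(frozenset(pool))
        rng = np.random.default_rng(23)
        expected = im.expected_fraction(n, k)
        covs = []
        for _ in range(trials):
            rep = ev.evaluate_sample(_uniform_sample(sub, k, rng), sub, k)
            covs.append(rep.coverage_fraction)
            assert rep.ideal_fraction == pytest.approx(expected)
        se = np.sqrt(expected * (1 - expected) / (n * trials))
        assert abs(np.mean(covs) - expected) < 3 * se

    def test_streaming_with_sqlite_store(self, toy_space, tmp_path):
        sample = (s for s in ["CCO", "CCO", "CCN", "C1CC"])
        rep = ev.evaluate_sample(
            sample, toy_space, unique_store_path=tmp_path / "uniq.db"
        )
        assert rep.unique_in_space == 2
        assert rep.total == 4

    def test_empty_sample_rejected(self, toy_space):
        with pytest.raises(ValueError):
            ev.evaluate_sample([], toy_space)


class TestCoverageUpperBound:
    def test_trained_model_never_beats_ideal(self, toy_space, coverage_trajectory):
        """The ideal uniform sampler upper-bounds trained-model coverage."""
        for epoch, rep in coverage_trajectory:
            p = rep.ideal_fraction
            se = np.sqrt(p * (1 - p) / toy_space.n)
            assert rep.coverage_fraction <= p + 3 * se, f"epoch {epoch}"

    def test_coverage_rises_then_plateaus(self, coverage_trajectory):
        covs = [rep.coverage_fraction for _, rep in coverage_trajectory]
        assert covs[-1] > covs[0]
        assert max(covs[-3:]) - min(covs[-3:]) < 0.05  # plateau at the tail


class TestFrequencySpectrum:
    def test_identical_sets_give_bimodal_spectrum(self, toy_space):
        half = set(sorted(toy_space.molecules)[: toy_space.n // 2])
        M = 4
        spec = ev.frequency_spectrum([half] * M, toy_space, k=100)
        hist = spec.histogram
        assert hist.sum() == toy_space.n
        occupied = {f for f, c in enumerate(hist) if c}
        assert occupied == {0, M}
        assert spec.mean == pytest.approx(M * len(half) / toy_space.n)

    def test_uniform_simulators_reproduce_binomial_null(self, toy_space):
        """M=5 ideal samplers: spectrum matches Binomial(5, p_cov) (chi-square)."""
        n, k, M = 200, 400, 5
        sub = cs.ReferenceSpace(frozenset(sorted(toy_space.molecules)[:n]))
        rng = np.random.default_rng(29)
        sets = [set(_uniform_sample(sub, k, rng)) for _ in range(M)]
        spec = ev.frequency_spectrum(sets, sub, k)
        null = spec.ideal_null()
        observed = spec.histogram
        expected = null.pmf * n
        # pool sparse tails for a valid chi-square
        keep = expected > 1.0
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        chi2 = ((obs - exp) ** 2 / np.maximum(exp, 1e-9)).sum()
        pval = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert pval > 0.01

    def test_foreign_molecule_rejected(self, toy_space):
        with pytest.raises(ValueError, match="not in space"):
            ev.frequency_spectrum([{"CCCCCCCCCC"}], toy_space, k=10)

    def test_no_models_rejected(self, toy_space):
        with pytest.raises(ValueError):
            ev.frequency_spectrum([], toy_space, k=10)


class TestFrequencyVsNll:
    def test_exact_construction_perfectly_monotone(self, toy_space):
        """NLL = -ln(f/M) by construction gives rho = -1."""
        M = 5
        mols = sorted(toy_space.molecules)
        freqs = {m: (i % M) + 1 for i, m in enumerate(mols)}
        spec = ev.FrequencySpectrum(
            num_models=M, k=100, frequencies=freqs, n=toy_space.n
        )
        nll = {m: -np.log(f / M) for m, f in freqs.items()}
        out = ev.frequency_vs_nll(spec, nll)
        assert out.attrs["spearman_rho"] == pytest.approx(-1.0)
        means = out.sort_values("frequency").mean_nll.to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_single_stratum_undefined(self, toy_space):
        freqs = {m: 2 for m in toy_space.molecules}
        spec = ev.FrequencySpectrum(num_models=3, k=10, frequencies=freqs, n=toy_space.n)
        out = ev.frequency_vs_nll(spec, {m: 1.0 for m in list(freqs)[:50]})
        assert np.isnan(out.attrs["spearman_rho"])

    def test_trained_models_show_negative_correlation(self, toy_space, toy_run):
        """Frequency across seeds anticorrelates with model NLL."""
        from chemcover.cli import derive_seed

        model = toy_run.model
        M, k = 3, 1500
        sets = []
        for m in range(M):
            sample = model.sample(k, seed=derive_seed(31, "freq", m))
            sets.append(
                {
                    c
                    for r in sample
                    if not r.truncated
                    and (c := cs.canonicalize(r.smiles)) is not None
                    and c in toy_space
                }
            )
        spec = ev.frequency_spectrum(sets, toy_space, k)
        mols = sorted(toy_space.molecules)
        nll = dict(zip(mols, model.nll_many(mols)))
        out = ev.frequency_vs_nll(spec, nll)
        assert out.attrs["spearman_rho"] < -0.3


class TestNgramAnalysis:
    def test_two_molecule_unigrams(self):
        space = cs.ReferenceSpace(frozenset({"CC", "CO"}))
        table = ev.ngram_analysis(space, None, order=1)
        pct = dict(zip(table.gram, table.percent))
        assert pct == {"C": 75.0, "O": 25.0}

    def test_percents_sum_to_100(self, toy_space):
        for order in (1, 2):
            table = ev.ngram_analysis(toy_space, None, order=order)
            assert table.percent.sum() == pytest.approx(100.0)

    def test_boundary_grams_flag(self):
        space = cs.ReferenceSpace(frozenset({"CC"}))
        without = ev.ngram_analysis(space, None, order=2)
        with_b = ev.ngram_analysis(space, None, order=2, include_boundary=True)
        assert set(without.gram) == {"CC"}
        assert set(with_b.gram) == {"^C", "CC", "C$"}

    def test_gram_only_in_never_sampled_has_zero_mean_frequency(self, toy_space):
        freqs = {m: (0 if "#" in m else 3) for m in toy_space.molecules}
        spec = ev.FrequencySpectrum(num_models=3, k=10, frequencies=freqs, n=toy_space.n)
        table = ev.ngram_analysis(toy_space, spec, order=1)
        assert table.loc[table.gram == "#", "mean_frequency"].item() == 0.0

    def test_rare_grams_in_trained_run_have_lower_frequency(self, toy_space, toy_run):
        from chemcover.cli import derive_seed

        M, k = 3, 1500
        sets = []
        for m in range(M):
            sample = toy_run.model.sample(k, seed=derive_seed(37, "ng", m))
            sets.append(
                {
                    c
                    for r in sample
                    if not r.truncated
                    and (c := cs.canonicalize(r.smiles)) is not None
                    and c in toy_space
                }
            )
        spec = ev.frequency_spectrum(sets, toy_space, k)
        table = ev.ngram_analysis(toy_space, spec, order=2)
        top = table.head(5).mean_frequency.mean()
        rare = table[table.percent < 1.0].mean_frequency.mean()
        assert rare < top

    def test_bad_order_rejected(self, toy_space):
        with pytest.raises(ValueError):
            ev.ngram_analysis(toy_space, None, order=3)
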