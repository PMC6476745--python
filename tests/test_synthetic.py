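"""Generator ground truth, depth propagation, read sampling and biomass."""

import numpy as np
import pandas as pd
import pytest

from sedistrat import (
    DomainParams,
    LayerScheme,
    SimParams,
    generate_biomass,
    generate_surface,
    propagate_depth,
    sample_reads,
    simulate,
)

SMALL_SCHEME = LayerScheme([(0, 2), (2, 4), (4, 6)])


def small_params(**kwargs):
    return SimParams(
        archaea=DomainParams(60, 0.0, 1.0, 200, SMALL_SCHEME),
        bacteria=DomainParams(80, 0.0, 1.0, 400, SMALL_SCHEME),
        **kwargs,
    )


class TestGenerateSurface:
    def test_determinism(self):
        p = small_params()
        a = generate_surface(p, "bacteria", np.random.default_rng(5))
        b = generate_surface(p, "bacteria", np.random.default_rng(5))
        pd.testing.assert_series_equal(a.surface, b.surface)
        pd.testing.assert_series_equal(a.lineages, b.lineages)

    def test_surface_sums_to_one(self):
        t = generate_surface(small_params(), "archaea", np.random.default_rng(0))
        assert t.surface.sum() == pytest.approx(1.0)

    def test_zero_persistent_fraction(self):
        t = generate_surface(
            small_params(persistent_fraction=0.0), "bacteria", np.random.default_rng(1)
        )
        assert not t.persistent.any()
        assert (t.decay >= 0.3).all()

    def test_persistent_fraction_within_binomial_error(self):
        p = SimParams(
            bacteria=DomainParams(2000, 0.0, 1.0, 400, SMALL_SCHEME),
            persistent_fraction=0.10,
        )
        t = generate_surface(p, "bacteria", np.random.default_rng(2))
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert abs(t.persistent.mean() - 0.10) < 3 * se

    def test_persistent_otus_enriched_in_deep_lineages(self):
        from sedistrat.synthetic import BACTERIAL_DEEP_LINEAGES

        p = SimParams(
            bacteria=DomainParams(3000, 0.0, 1.0, 400, SMALL_SCHEME),
            persistent_fraction=0.5,
        )
        t = generate_surface(p, "bacteria", np.random.default_rng(3))
        deep = set(BACTERIAL_DEEP_LINEAGES)
        frac_deep_persistent = t.lineages[t.persistent].isin(deep).mean()
        frac_deep_transient = t.lineages[~t.persistent].isin(deep).mean()
        assert frac_deep_persistent > 0.6 > 0.4 > frac_deep_transient


class TestPropagateDepth:
    def test_zero_decay_preserves_composition(self):
        p = small_params(persistent_fraction=1.0, persistent_decay_max=0.0)
        t = generate_surface(p, "bacteria", np.random.default_rng(4))
        comps, _ = propagate_depth(t, p)
        for col in comps.columns:
            np.testing.assert_allclose(comps[col].to_numpy(), t.surface.to_numpy())

    def test_single_persistent_dominates_at_depth(self):
        deep_scheme = LayerScheme([(0, 2), (48, 50)])
        p = SimParams(
            bacteria=DomainParams(50, 0.0, 1.0, 400, deep_scheme),
            persistent_fraction=0.0,
        )
        t = generate_surface(p, "bacteria", np.random.default_rng(6))
        t.persistent.iloc[0] = True
        t.decay.iloc[0] = 0.0
        comps, _ = propagate_depth(t, p)
        assert comps.iloc[0, -1] > 0.999

    def test_neutral_survival_matches_analytic_expectation(self):
        scheme = LayerScheme([(i, i + 1) for i in range(4)])
        p = SimParams(
            bacteria=DomainParams(50, 0.0, 1.0, 200, scheme),
            assembly_model="neutral_turnover",
            turnover_rate=0.3,
        )
        rng = np.random.default_rng(8)
        surv = np.zeros(4)
        n_runs = 400
        for _ in range(n_runs):
            t = generate_surface(p, "bacteria", rng)
            comps, _ = propagate_depth(t, p, rng=rng)
            original = comps.loc[t.otu_ids]
            surv += (original.to_numpy() > 0).mean(axis=0)
        surv /= n_runs
        for k in range(4):
            expect = 0.7**k
            se = np.sqrt(expect * (1 - expect) / (50 * n_runs)) + 1e-9
            assert abs(surv[k] - expect) < 4 * se

    def test_neutral_extends_truth_with_novel_otus(self):
        p = small_params(assembly_model="neutral_turnover")
        rng = np.random.default_rng(9)
        t = generate_surface(p, "bacteria", rng)
        comps, extended = propagate_depth(t, p, rng=rng)
        novel = [o for o in extended.otu_ids if "Novel" in o]
        assert novel and not extended.persistent.loc[novel].any()
        np.testing.assert_allclose(comps.sum(axis=0).to_numpy(), 1.0)


class TestSampleReads:
    def _comps_truth(self, seed=10):
        p = small_params()
        rng = np.random.default_rng(seed)
        t = generate_surface(p, "archaea", rng)
        comps, _ = propagate_depth(t, p)
        return p, t, comps, rng

    def test_column_sums_equal_library_size(self):
        p, t, comps, rng = self._comps_truth()
        table = sample_reads(comps, t, p, rng)
        assert (table.totals() == p.archaea.library_size).all()
        assert len(table.samples) == p.n_cores * len(SMALL_SCHEME)

    def test_zero_abundance_never_sampled(self):
        p, t, comps, rng = self._comps_truth()
        comps.iloc[0] = 0.0
        comps = comps / comps.sum(axis=0)
        table = sample_reads(comps, t, p, rng)
        assert (table.counts.iloc[0] == 0).all()

    def test_multinomial_mean_tracks_truth(self):
        p, t, comps, rng = self._comps_truth()
        lib = p.archaea.library_size
        reps = 500
        acc = np.zeros(len(comps))
        for _ in range(reps):
            table = sample_reads(comps, t, p, rng)
            col = table.counts[[s.sample_id for s in table.samples if s.layer_top_cm == 0]]
            acc += col.mean(axis=1).to_numpy()
        acc /= reps
        expected = comps["0-2"].to_numpy() * lib
        # overdispersed multinomial: allow generous monte-carlo + Dirichlet slack
        big = expected > 5
        assert np.allclose(acc[big], expected[big], rtol=0.15)


class TestBiomass:
    def test_flat_when_no_decay_no_noise(self):
        p = small_params()
        profile = generate_biomass(
            p,
            np.random.default_rng(0),
            noise_sigma=0.0,
            defaults={"dna_decay_per_cm": 0.0, "rna_decay_per_cm": 0.0,
                      "brfa_decay_per_cm": 0.0, "rna_detection_limit_ng_g": 0.0},
        )
        dna = profile.analyte("DNA")["value"]
        assert dna.nunique() == 1

    def test_noise_free_profiles_decay_monotonically(self):
        profile = generate_biomass(SimParams(), np.random.default_rng(0), noise_sigma=0.0)
        for analyte in ("DNA", "BrFA"):
            vals = profile.analyte(analyte).sort_values("layer_mid_cm")["value"].to_numpy()
            assert (np.diff(vals) < 0).all()

    def test_default_rna_below_detection_at_depth(self):
        profile = generate_biomass(SimParams(), np.random.default_rng(0), noise_sigma=0.0)
        rna = profile.analyte("RNA")
        assert rna["below_detection"].any()
        ratios = profile.ratio_profile("DNA", "RNA")
        assert ratios["value"].isna().any()
        assert ratios["value"].notna().any()


class TestSimulate:
    def test_full_determinism_under_seed(self):
        p = small_params()
        a = simulate(p, seed=42)
        b = simulate(p, seed=42)
        for domain in ("archaea", "bacteria"):
            pd.testing.assert_frame_equal(
                a.tables[domain].counts, b.tables[domain].counts
            )
        pd.testing.assert_frame_equal(a.geochem.data, b.geochem.data)

    def test_two_layer_schemes_emitted(self):
        res = simulate(seed=0)
        arch_bins = {(s.layer_top_cm, s.layer_bottom_cm) for s in res.tables["archaea"].samples}
        bact_bins = {(s.layer_top_cm, s.layer_bottom_cm) for s in res.tables["bacteria"].samples}
        assert (0.0, 1.0) in arch_bins and (0.0, 2.0) in bact_bins
        assert (15.0, 16.0) not in arch_bins

    def test_written_bundle_parses_back(self, tmp_path):
        from sedistrat import read_table
        from sedistrat.io import read_metadata

        p = small_params()
        simulate(p, seed=1, outdir=tmp_path, fmt="mothur")
        meta = read_metadata(tmp_path / "samples.tsv")
        back = read_table(
            tmp_path / "archaea.shared",
            fmt="mothur",
            taxonomy=tmp_path / "archaea.cons.taxonomy",
            metadata=meta,
        )
        assert (back.totals() == p.archaea.library_size).all()
        assert (tmp_path / "sim_params.yaml").exists()
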