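"""Selection-protocol simulator: masks, mutagenesis, enrichment dynamics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from noisevolve import cytometry, evolution_sim as es, synthio
from noisevolve.cytometry import EventTable


def logged_table(gfp, mch):
    n = len(gfp)
    df = pd.DataFrame({
        "FSC_A": np.full(n, 5e4), "FSC_W": np.full(n, 100.0),
        "SSC_A": np.full(n, 2e4),
        "GFP": np.asarray(gfp, float), "mCherry": np.asarray(mch, float),
    })
    return EventTable(df, log_channels=frozenset({"GFP", "mCherry"}))


class TestEmsMutagenize:
    def wt_pop(self, n=1_000_000):
        wt = es.Lineage(0, "wild-type", synthio.ReporterModel(), 1.0, n)
        return es.Population([wt])

    def test_zero_fraction_is_identity(self):
        pop = self.wt_pop()
        out = es.ems_mutagenize(pop, 0.0, es.MutationEffects(), seed=0)
        assert out.size == pop.size and len(out.lineages) == 1

    def test_founder_counts_within_binomial_ci(self):
        eff = es.MutationEffects(class_probs={"noise-up": 0.001, "neutral": 0.999})
        out = es.ems_mutagenize(self.wt_pop(), 1.0, eff, seed=1)
        n_up = sum(l.abundance for l in out.lineages if l.klass == "noise-up")
        lo, hi = stats.binom.interval(0.999, 1_000_000, 0.001)
        assert lo <= n_up <= hi
        assert out.size == 1_000_000  # abundance conserved exactly

    def test_seeded_run_reproducible(self):
        eff = es.MutationEffects()
        a = es.ems_mutagenize(self.wt_pop(), 0.5, eff, seed=2)
        b = es.ems_mutagenize(self.wt_pop(), 0.5, eff, seed=2)
        assert [(l.klass, l.abundance, l.model) for l in a.lineages] == \
               [(l.klass, l.abundance, l.model) for l in b.lineages]

    def test_rejects_excess_probabilities(self):
        with pytest.raises(ValueError, match="> 1"):
            es.MutationEffects(class_probs={"noise-up": 0.7, "neutral": 0.7})


class TestOutermostSelection:
    def test_exact_floor_count(self, rng):
        ev = logged_table(rng.normal(3, 0.3, 100_000), rng.normal(3, 0.3, 100_000))
        mask = es.outermost_selection(ev, 0.10)
        assert mask.sum() == 10_000

    def test_selected_distances_dominate_unselected(self, rng):
        from scipy.spatial.distance import mahalanobis

        g = rng.normal(0, 1, 2_000)
        m = rng.normal(0, 1, 2_000)
        ev = logged_table(g, m)
        mask = es.outermost_selection(ev, 0.10)
        # independent oracle: per-point Mahalanobis distance via scipy
        pts = np.column_stack([g, m])
        vi = np.linalg.inv(np.cov(pts, rowvar=False))
        center = pts.mean(axis=0)
        d = np.array([mahalanobis(p, center, vi) for p in pts])
        assert d[mask].min() >= d[~mask].max() - 1e-9

    def test_identical_events_tie_break_by_index(self):
        ev = logged_table(np.ones(50), np.ones(50))
        with pytest.warns(UserWarning, match="singular"):
            mask = es.outermost_selection(ev, 0.10)
        assert list(np.flatnonzero(mask)) == [0, 1, 2, 3, 4]


class TestQuadrantMask:
    def test_independent_channels_split_quarterly(self, rng):
        ev = logged_table(rng.normal(0, 1, 40_000), rng.normal(0, 1, 40_000))
        for q in ("QI", "QII", "QIV"):
            frac = es.quadrant_mask(ev, q).mean()
            assert frac == pytest.approx(0.25, abs=0.01)

    def test_quadrants_disjoint(self, rng):
        ev = logged_table(rng.normal(0, 1, 1_000), rng.normal(0, 1, 1_000))
        qi = es.quadrant_mask(ev, "QI")
        qii = es.quadrant_mask(ev, "QII")
        qiv = es.quadrant_mask(ev, "QIV")
        assert not (qi & qii).any() and not (qi & qiv).any() and not (qii & qiv).any()
        union = es.quadrant_mask(ev, "QII+QIV")
        assert np.array_equal(union, qii | qiv)

    def test_boundary_events_fall_at_or_below(self):
        ev = logged_table([1.0, 1.0, 2.0], [1.0, 2.0, 2.0])
        # medians: gfp=1, mch=2; events at a median go to the at/below side
        qi = es.quadrant_mask(ev, "QI")
        assert not qi[0] and not qi[1]


class TestSortRecover:
    def test_single_lineage_survives_sort(self):
        wt = es.Lineage(0, "wild-type", synthio.ReporterModel(), 1.0, 100_000)
        out = es.sort_step(es.Population([wt]), "QII+QIV",
                           es.ProtocolConfig(), seed=0)
        assert out.class_frequencies()["wild-type"] == 1.0
        assert out.size > 0

    def test_reporter_defect_counterselected_by_qi_sort(self):
        wt = es.Lineage(0, "wild-type", synthio.ReporterModel(), 1.0, 50_000)
        broken = synthio.ReporterModel(mu_gfp=12.0)  # GFP at background
        bad = es.Lineage(1, "gfp-defect", broken, 1.0, 50_000)
        depleted = 0
        for seed in range(5):
            after = es.sort_step(es.Population([wt, bad]), "QI",
                                 es.ProtocolConfig(), seed=seed)
            depleted += after.class_frequencies()["gfp-defect"] < 0.5
        assert depleted >= 4

    def test_recover_total_is_exact_and_neutral(self):
        a = es.Lineage(0, "wild-type", synthio.ReporterModel(), 1.0, 5_000)
        b = es.Lineage(1, "neutral", synthio.ReporterModel(), 1.0, 5_000)
        out = es.recover(es.Population([a, b]), 80_000, generations=10, seed=3)
        assert out.size == 80_000
        freq = out.class_frequencies()["neutral"]
        lo, hi = np.array(stats.binom.interval(0.999, 80_000, 0.5)) / 80_000
        assert lo <= freq <= hi

    def test_mito_defect_depleted_by_glycerol_recovery(self):
        wt = es.Lineage(0, "wild-type", synthio.ReporterModel(), 1.0, 5_000)
        mito = es.Lineage(1, "mito-defect", synthio.ReporterModel(),
                          es.MITO_GROWTH, 5_000)
        out = es.recover(es.Population([wt, mito]), 100_000,
                         generations=10, seed=4)
        assert out.class_frequencies()["mito-defect"] < 0.01

    def test_recover_identity_single_lineage(self):
        wt = es.Lineage(0, "wild-type", synthio.ReporterModel(), 1.0, 1_000)
        out = es.recover(es.Population([wt]), 1_000, generations=5, seed=0)
        assert out.size == 1_000 and len(out.lineages) == 1

    def test_extinguished_selection_raises(self):
        with pytest.raises(es.SelectionExtinguishedError):
            es.recover(es.Population([]), 100, 1.0, 0)


class TestRunProtocol:
    def test_no_mutagenesis_keeps_fano_flat(self):
        cfg = es.ProtocolConfig(mutant_fraction=0.0, n_rounds=1)
        traj = es.run_protocol(cfg, seed=5)
        wt = traj[traj.lineage_class == "wild-type"]
        assert (wt.frequency == 1.0).all()
        first = wt.fano_gfp.iloc[0]
        last = wt.fano_gfp.iloc[-1]
        assert last == pytest.approx(first, rel=0.25)  # sampling error only

    def test_noise_up_lineages_enrich(self):
        eff = es.MutationEffects(class_probs={"noise-up": 1e-3, "neutral": 0.999})
        cfg = es.ProtocolConfig(mutant_fraction=1.0, effects=eff)
        wins = 0
        for seed in range(10):
            traj = es.run_protocol(cfg, seed)
            nu = traj[traj.lineage_class == "noise-up"]
            initial = nu[nu.step == "post-EMS"].frequency.item()
            final = nu[nu.step == nu.step.iloc[-1]].frequency.item()
            wins += final > initial
        assert wins >= 9

    def test_enrichment_monotone_in_sigma_multiplier(self):
        means = []
        for mult in (1.0, 1.5, 2.0):
            eff = es.MutationEffects(class_probs={"noise-up": 0.01, "neutral": 0.99},
                                     noise_up_range=(mult, mult))
            cfg = es.ProtocolConfig(mutant_fraction=1.0, effects=eff)
            finals = []
            for seed in range(5):
                traj = es.run_protocol(cfg, seed)
                nu = traj[traj.lineage_class == "noise-up"]
                finals.append(nu[nu.step == nu.step.iloc[-1]].frequency.item())
            means.append(np.mean(finals))
        assert means[0] < means[1] < means[2]

    def test_noise_up_beats_general_activator(self):
        """The alternating QII/QIV + QI schedule favors noise mutants over
        general activators that move both reporters together."""
        wt_model = synthio.ReporterModel()
        noisy = es.Lineage(1, "noise-up",
                           synthio.ReporterModel(sigma_ext=0.5,
                                                 sigma_int_gfp=0.3,
                                                 sigma_int_mcherry=0.3),
                           1.0, 1_000)
        activ = es.Lineage(2, "general-up",
                           synthio.ReporterModel(mu_gfp=3600.0, mu_mcherry=2700.0),
                           1.0, 1_000)
        cfg = es.ProtocolConfig()
        final_noise, final_activ = [], []
        for seed in range(5):
            wt = es.Lineage(0, "wild-type", wt_model, 1.0, 98_000)
            pop = es.Population([wt, noisy, activ])
            rng = np.random.default_rng(seed)
            for gate in ("QII+QIV", "QI", "QII+QIV", "QI"):
                pop = es.sort_step(pop, gate, cfg, int(rng.integers(2**31)))
                pop = es.recover(pop, cfg.recovery_size,
                                 cfg.recovery_generations, int(rng.integers(2**31)))
            freqs = pop.class_frequencies()
            final_noise.append(freqs["noise-up"])
            final_activ.append(freqs["general-up"])
        assert np.mean(final_noise) > np.mean(final_activ)

    def test_full_run_bit_reproducible(self):
        cfg = es.ProtocolConfig(n_rounds=1)
        t1 = es.run_protocol(cfg, seed=42)
        t2 = es.run_protocol(cfg, seed=42)
        pd.testing.assert_frame_equal(t1, t2)
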