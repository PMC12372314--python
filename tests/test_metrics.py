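"""IRC/ISC metrics: Fisher z, censoring-aware correlations, reference and
group similarity, event magnitude."""
import itertools

import numpy as np
import pytest

import socialbrain as sb
from socialbrain.errors import DataError

ATLAS13 = dict(sb.SimConfig().roi_networks)


def tc13(values, censor=None):
    return sb.RoiTimecourseSet(
        values=values,
        roi_labels=list(ATLAS13),
        network_of=ATLAS13,
        tr_seconds=0.72,
        censor=sb.CensorMask(censor) if censor is not None else None,
    )


def ntc(values, censor=None, network="ToM"):
    values = np.asarray(values, dtype=float)
    if censor is None:
        censor = np.zeros(len(values), dtype=bool)
    return sb.NetworkTimecourse(
        values=values, network=network, censor=sb.CensorMask(censor)
    )


class TestFisherZ:
    def test_values(self):
        assert sb.fisher_z(0.0) == 0.0
        assert sb.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert sb.fisher_z(-0.5) == pytest.approx(-0.5493, abs=1e-4)

    def test_clipping_keeps_unity_finite(self):
        z = sb.fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            sb.fisher_z(np.nan)
        with pytest.raises(DataError):
            sb.fisher_z(1.5)


class TestPairwiseCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(20.0)
        assert sb.pairwise_correlation(x, 2 * x + 3) == pytest.approx(1.0)

    def test_censored_point_excluded(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 100.0])
        mask_y = sb.CensorMask(np.array([False, False, False, True]))
        r = sb.pairwise_correlation(x, y, mask_y=mask_y, min_points=3)
        assert r == pytest.approx(1.0)

    def test_too_few_joint_points_rejected(self):
        x = np.arange(12.0)
        mask = sb.CensorMask(np.arange(12) < 5)
        with pytest.raises(DataError):
            sb.pairwise_correlation(x, x, mask_x=mask, min_points=10)

    def test_null_distribution(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            val = sb.pairwise_correlation(r.normal(size=500), r.normal(size=500))
            hits += abs(val) < 0.15
        assert hits >= 95


class TestIrcSummary:
    def naive_summary(self, tc):
        """Triple-loop oracle: per-pair Pearson on uncensored TRs, Fisher z,
        then plain means over the three pair families."""
        valid = ~tc.censor.censored
        tom = tc.rois_in("ToM")
        pain = tc.rois_in("Pain")

        def r(a, b):
            x, y = tc.column(a)[valid], tc.column(b)[valid]
            xm, ym = x - x.mean(), y - y.mean()
            return float(
                (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
            )

        def z(v):
            return float(np.arctanh(np.clip(v, -(1 - 1e-7), 1 - 1e-7)))

        wt = [z(r(a, b)) for a, b in itertools.combinations(tom, 2)]
        wp = [z(r(a, b)) for a, b in itertools.combinations(pain, 2)]
        ac = [z(r(a, b)) for a in tom for b in pain]
        return np.mean(wt), np.mean(wp), np.mean(ac), (len(wt), len(wp), len(ac))

    def test_matches_naive_oracle(self, rng):
        for _ in range(3):
            censor = rng.random(60) < 0.1
            tc = tc13(rng.normal(size=(60, 13)), censor)
            got = sb.irc_summary(tc)
            wt, wp, ac, counts = self.naive_summary(tc)
            assert counts == (15, 21, 42)
            assert got.within_tom_z == pytest.approx(wt, abs=1e-12)
            assert got.within_pain_z == pytest.approx(wp, abs=1e-12)
            assert got.across_z == pytest.approx(ac, abs=1e-12)

    def test_shared_template_equalizes_within_and_across(self, rng):
        f = rng.normal(size=800)
        vals = f[:, None] + 0.5 * rng.normal(size=(800, 13))
        got = sb.irc_summary(tc13(vals))
        assert got.within_tom_z == pytest.approx(got.across_z, abs=0.1)

    def test_orthogonal_templates_separate_networks(self, rng):
        f_tom = rng.normal(size=2000)
        f_pain = rng.normal(size=2000)
        cols = []
        for roi, net in ATLAS13.items():
            f = f_tom if net == "ToM" else f_pain
            cols.append(f + 0.5 * rng.normal(size=2000))
        got = sb.irc_summary(tc13(np.column_stack(cols)))
        assert abs(got.across_z) < 0.1
        assert got.within_tom_z > 0.5
        assert got.within_pain_z > 0.5

    def test_mean_of_z_not_z_of_mean(self):
        # fixture where the two conventions differ: r pairs (0.9, 0.1)
        t = np.arange(400)
        base = np.sin(t / 7.0) + np.cos(t / 13.0)
        rng = np.random.default_rng(0)
        a = base + 0.1 * rng.normal(size=400)
        b = base + 0.1 * rng.normal(size=400)
        c = 4.0 * rng.normal(size=400)
        atlas = {"x": "ToM", "y": "ToM", "z": "ToM", "p": "Pain", "q": "Pain"}
        tc = sb.RoiTimecourseSet(
            values=np.column_stack([a, b, c, rng.normal(size=400), rng.normal(size=400)]),
            roi_labels=list(atlas),
            network_of=atlas,
            tr_seconds=0.72,
        )
        got = sb.irc_summary(tc)
        valid_r = np.corrcoef(tc.values.T)
        pairs = [valid_r[0, 1], valid_r[0, 2], valid_r[1, 2]]
        mean_of_z = np.mean([np.arctanh(r) for r in pairs])
        z_of_mean = np.arctanh(np.mean(pairs))
        assert got.within_tom_z == pytest.approx(mean_of_z, abs=1e-10)
        assert abs(got.within_tom_z - z_of_mean) > 0.01


class TestSimilarityToReference:
    def test_two_identical_reference_subjects_loo(self, rng):
        x = rng.normal(size=100)
        refs = [ntc(x), ntc(x)]
        z = sb.similarity_to_reference(refs[0], refs, leave_self_out=True, subject_index=0)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_noise_subject_near_zero_over_seeds(self):
        zs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            shared = r.normal(size=300)
            refs = [ntc(shared + 0.1 * r.normal(size=300)) for _ in range(5)]
            subject = ntc(r.normal(size=300))
            zs.append(sb.similarity_to_reference(subject, refs))
        assert abs(np.mean(zs)) < 0.05

    def test_non_member_uses_full_group_average(self, rng):
        refs = [ntc(rng.normal(size=120)) for _ in range(4)]
        subject = ntc(rng.normal(size=120))
        z = sb.similarity_to_reference(subject, refs, leave_self_out=False)
        stack = np.stack([r.values for r in refs])
        expected = np.arctanh(
            np.clip(np.corrcoef(subject.values, stack.mean(axis=0))[0, 1],
                    -(1 - 1e-7), 1 - 1e-7)
        )
        assert z == pytest.approx(float(expected), abs=1e-12)

    def test_reference_censoring_drops_subjects_per_timepoint(self, rng):
        x = rng.normal(size=50)
        good = ntc(x)
        censored_all = np.zeros(50, dtype=bool)
        censored_all[:25] = True
        noisy = ntc(np.where(censored_all, 1e6, x), censored_all)
        subject = ntc(x + 0.01 * rng.normal(size=50))
        z = sb.similarity_to_reference(subject, [good, noisy])
        assert z > 2.0  # the censored garbage never enters the average

    def test_loo_needs_two_reference_subjects(self, rng):
        refs = [ntc(rng.normal(size=50))]
        with pytest.raises(DataError):
            sb.similarity_to_reference(refs[0], refs, leave_self_out=True, subject_index=0)


class TestGroupSimilarity:
    def test_matrix_exactly_symmetric(self, rng):
        tcs = [ntc(rng.normal(size=80)) for _ in range(6)]
        z = sb.pairwise_z_matrix(tcs)
        assert np.array_equal(z, z.T, equal_nan=True)

    def test_two_per_group_within_equals_single_pair(self, rng):
        tcs = [ntc(rng.normal(size=80)) for _ in range(4)]
        groups = ["NT", "NT", "ASD", "ASD"]
        out = sb.group_similarity_summary(tcs, groups)
        z = sb.pairwise_z_matrix(tcs)
        assert out.loc[0, "within_group_z"] == pytest.approx(z[0, 1])
        assert out.loc[2, "within_group_z"] == pytest.approx(z[2, 3])

    def test_across_group_grand_means_agree(self, rng):
        tcs = [ntc(rng.normal(size=80)) for _ in range(9)]
        groups = ["NT"] * 5 + ["ASD"] * 4
        out = sb.group_similarity_summary(tcs, groups)
        labels = np.array(groups)
        nt_mean = out.loc[labels == "NT", "across_group_z"].mean()
        asd_mean = out.loc[labels == "ASD", "across_group_z"].mean()
        assert nt_mean == pytest.approx(asd_mean, abs=1e-12)

    def test_default_synthetic_ordering(self):
        # within-NT > across-group > within-ASD at the default loadings
        from socialbrain.synthetic import subject_seed

        cfg = sb.SimConfig(seed=4, n_per_group={"ASD": 12, "NT": 12})
        t = sb.generate_templates(cfg)
        tcs, groups = [], []
        idx = 0
        for g, n in cfg.n_per_group.items():
            for _ in range(n):
                tc = sb.generate_subject_timecourses(
                    cfg, t, g, subject_seed(cfg.seed, idx)
                )
                tcs.append(sb.network_average(tc, "ToM"))
                groups.append(g)
                idx += 1
        out = sb.group_similarity_summary(tcs, groups)
        labels = np.array(groups)
        w_nt = out.loc[labels == "NT", "within_group_z"].mean()
        w_asd = out.loc[labels == "ASD", "within_group_z"].mean()
        across = out.loc[labels == "NT", "across_group_z"].mean()
        assert w_nt > across > w_asd


class TestEventMagnitude:
    def test_plain_window_mean(self):
        tc = ntc(np.array([0.0, 0.5, 1.0, 1.5, 0.0]))
        assert sb.event_magnitude(tc, (1, 4)) == pytest.approx(1.0)

    def test_censored_tr_dropped(self):
        censor = np.array([False, False, True, False, False])
        tc = ntc(np.array([0.0, 0.5, 99.0, 1.5, 0.0]), censor)
        assert sb.event_magnitude(tc, (1, 4)) == pytest.approx(1.0)

    def test_fully_censored_window_is_missing(self):
        censor = np.array([False, True, True, True, False])
        tc = ntc(np.zeros(5), censor)
        assert np.isnan(sb.event_magnitude(tc, (1, 4)))

    def test_window_bounds_checked(self):
        tc = ntc(np.zeros(5))
        with pytest.raises(DataError):
            sb.event_magnitude(tc, (3, 9))
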