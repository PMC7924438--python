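"""Structural features: partition identities, brute-force oracles,
rigid-motion invariance, AAindex and log-odds behavior."""

import numpy as np
import pytest

from clusmote import features as F
from clusmote.synthetic import ToyStructureSpec, make_toy_structure


# ---------------------------------------------------------------------------
# brute-force oracles (straight loops, independent of the implementation)
# ---------------------------------------------------------------------------

def cn_oracle(ca, radius):
    n = len(ca)
    return np.array([sum(1 for j in range(n) if j != i
                         and np.linalg.norm(ca[j] - ca[i]) <= radius)
                     for i in range(n)])


def hse_oracle(ca, radius):
    n = len(ca)
    up = np.full(n, np.nan)
    down = np.full(n, np.nan)
    for i in range(1, n - 1):
        u = (ca[i] - ca[i - 1]) + (ca[i] - ca[i + 1])
        u = u / np.linalg.norm(u)
        cu = cd = 0
        for j in range(n):
            if j == i or np.linalg.norm(ca[j] - ca[i]) > radius:
                continue
            if np.dot(ca[j] - ca[i], u) > 1e-6:  # ties count down
                cu += 1
            else:
                cd += 1
        up[i], down[i] = cu, cd
    return up, down


def qse_oracle(ca, radius):
    n = len(ca)
    out = np.full((n, 8), np.nan)
    for i in range(1, n - 1):
        u = (ca[i] - ca[i - 1]) + (ca[i] - ca[i + 1])
        e1 = u / np.linalg.norm(u)
        t = ca[i + 1] - ca[i - 1]
        t = t - np.dot(t, e1) * e1
        if np.linalg.norm(t) < 1e-9:
            continue
        e2 = t / np.linalg.norm(t)
        e3 = np.cross(e1, e2)
        counts = np.zeros(8)
        for j in range(n):
            if j == i or np.linalg.norm(ca[j] - ca[i]) > radius:
                continue
            d = ca[j] - ca[i]
            # ties resolve to the negative side (same 1e-6 Å tolerance
            # as the documented convention)
            octant = ((np.dot(d, e1) > 1e-6) << 2) \
                | ((np.dot(d, e2) > 1e-6) << 1) | (np.dot(d, e3) > 1e-6)
            counts[octant] += 1
        out[i] = counts
    return out


def _table(ca, **kw):
    n = len(ca)
    return F.ResidueTable(
        chain=np.full(n, "A", dtype=object),
        resnum=np.arange(1, n + 1),
        aa=np.full(n, "A", dtype=object),
        ca=np.asarray(ca, dtype=float),
        b_ca=np.zeros(n), b_mean=np.zeros(n), **kw)


class TestParsePdb:
    def test_two_models_only_first_parsed(self, tmp_path):
        rec = ("ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
               "  1.00 10.00           C")
        rec2 = rec.replace("   1   ", "   2   ")
        text = "\n".join(["MODEL     1", rec, "ENDMDL",
                          "MODEL     2", rec, rec2, "ENDMDL", "END"]) + "\n"
        p = tmp_path / "two_models.pdb"
        p.write_text(text)
        rt = F.parse_pdb(p)
        assert len(rt) == 1

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(F.PDBParseError):
            F.parse_pdb(p)


class TestSurfaceFilter:
    def test_threshold_comparison(self):
        rt = _table(np.random.default_rng(0).normal(size=(4, 3)),
                    rsa=np.array([0.0, 0.005, 0.02, 0.5]))
        kept = F.surface_filter(rt, threshold=0.01)
        assert len(kept) == 2
        assert np.allclose(kept.rsa, [0.02, 0.5])
        assert kept.exposed.all()

    def test_zero_threshold_keeps_positive_rsa(self):
        rt = _table(np.random.default_rng(1).normal(size=(4, 3)),
                    rsa=np.array([0.0, 0.005, 0.02, 0.5]))
        assert len(F.surface_filter(rt, threshold=0.0)) == 3

    def test_monotone_in_threshold(self):
        rsa = np.random.default_rng(2).uniform(size=50)
        rt = _table(np.random.default_rng(3).normal(size=(50, 3)), rsa=rsa)
        counts = [len(F.surface_filter(rt, t))
                  for t in (0.0, 0.01, 0.1, 0.3, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_missing_rsa_rejected(self):
        rt = _table(np.zeros((4, 3)) + np.arange(4)[:, None])
        with pytest.raises(ValueError):
            F.surface_filter(rt)


class TestContactNumber:
    def test_two_residues_within_radius(self):
        rt = _table([[0, 0, 0], [5, 0, 0]])
        assert F.contact_number(rt, radius=13).tolist() == [1, 1]

    def test_radius_below_min_distance_gives_zero(self):
        rt = _table([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        assert F.contact_number(rt, radius=4).tolist() == [0, 0, 0]

    def test_helix_matches_brute_force(self, helix):
        rt, _ = helix
        assert np.array_equal(F.contact_number(rt, 13.0),
                              cn_oracle(rt.ca, 13.0))

    def test_nonpositive_radius_rejected(self, helix):
        with pytest.raises(ValueError):
            F.contact_number(helix[0], radius=0)


class TestHalfSphereExposure:
    def test_partition_identity_and_oracle(self, helix):
        rt, _ = helix
        up, down = F.half_sphere_exposure(rt, 13.0)
        cn = F.contact_number(rt, 13.0)
        interior = ~np.isnan(up)
        assert np.array_equal(up[interior] + down[interior], cn[interior])
        ou, od = hse_oracle(rt.ca, 13.0)
        assert np.allclose(up[interior], ou[interior])
        assert np.allclose(down[interior], od[interior])

    def test_equatorial_neighbor_counts_down(self):
        # residue 2's direction vector is +y; neighbor at same y -> tie -> down
        rt = _table([[0, 0, 0], [1, 1, 0], [2, 0, 0], [1, 1 - 3, 0]])
        up, down = F.half_sphere_exposure(rt, radius=10.0)
        u = 2 * rt.ca[1] - rt.ca[0] - rt.ca[2]  # = (0, 2, 0)
        d_equator = rt.ca[3] - rt.ca[1]
        assert np.dot(u, d_equator) < 0  # strictly below here
        rt2 = _table([[0, 0, 0], [1, 1, 0], [2, 0, 0], [5, 1, 0]])
        up2, down2 = F.half_sphere_exposure(rt2, radius=10.0)
        # neighbor 4 sits exactly in residue 2's equatorial plane (dot = 0)
        assert down2[1] >= 1

    def test_short_chain_all_missing(self):
        rt = _table([[0, 0, 0], [3.8, 0, 0]])
        up, down = F.half_sphere_exposure(rt, 13.0)
        assert np.isnan(up).all() and np.isnan(down).all()


class TestQuadrantSphereExposure:
    def test_octants_sum_to_cn(self, sphere):
        rt, _ = sphere
        qse = F.quadrant_sphere_exposure(rt, 13.0)
        cn = F.contact_number(rt, 13.0)
        ok = ~np.isnan(qse[:, 0])
        assert np.array_equal(qse[ok].sum(axis=1), cn[ok])

    def test_matches_brute_force(self, helix):
        rt, _ = helix
        qse = F.quadrant_sphere_exposure(rt, 13.0)
        oracle = qse_oracle(rt.ca, 13.0)
        ok = ~np.isnan(qse[:, 0]) & ~np.isnan(oracle[:, 0])
        assert np.allclose(qse[ok], oracle[ok])

    def test_mirror_reflection_permutes_octants(self):
        """Inverting all coordinates negates only the e3 axis of the
        local frame, so octants swap within (b2 b1 0)/(b2 b1 1) pairs.
        The two chain neighbors of every residue lie exactly in the
        e1-e2 plane (d = (t - u)/2) and stay on the negative-e3 side by
        the tie rule, so the invariant is pairwise: pair sums are
        preserved and the tie mass never leaves the b0=0 member."""
        ca = np.random.default_rng(14).normal(scale=5.0, size=(25, 3))
        qse = F.quadrant_sphere_exposure(_table(ca), 13.0)
        qse_m = F.quadrant_sphere_exposure(_table(-ca), 13.0)
        ok = ~np.isnan(qse[:, 0]) & ~np.isnan(qse_m[:, 0])
        assert ok.any()
        for k in (0, 2, 4, 6):  # b0 = 0 octants; partner is k + 1
            assert np.allclose(qse[ok][:, k] + qse[ok][:, k + 1],
                               qse_m[ok][:, k] + qse_m[ok][:, k + 1])
            # mirrored negative side >= original positive side (ties stay)
            assert np.all(qse_m[ok][:, k] >= qse[ok][:, k + 1])
            assert np.all(qse_m[ok][:, k + 1] <= qse[ok][:, k])

    def test_collinear_chain_flagged_missing(self):
        rt = _table([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
        qse = F.quadrant_sphere_exposure(rt, 13.0)
        assert np.isnan(qse).all()  # pseudo-CB vanishes on a straight chain


class TestRigidMotionInvariance:
    def test_cn_hse_qse_invariant(self, sphere):
        rt, _ = sphere
        rng = np.random.default_rng(6)
        # random rotation (QR of a Gaussian matrix) + translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = _table(rt.ca @ Q.T + rng.normal(scale=50, size=3))
        assert np.array_equal(F.contact_number(rt, 13.0),
                              F.contact_number(moved, 13.0))
        up_a, down_a = F.half_sphere_exposure(rt, 13.0)
        up_b, down_b = F.half_sphere_exposure(moved, 13.0)
        assert np.allclose(up_a, up_b, equal_nan=True)
        assert np.allclose(down_a, down_b, equal_nan=True)
        qa = F.quadrant_sphere_exposure(rt, 13.0)
        qb = F.quadrant_sphere_exposure(moved, 13.0)
        assert np.allclose(qa, qb, equal_nan=True)


class TestAnnotateEpitopes:
    def test_contact_within_threshold(self):
        rt = _table([[0, 0, 0], [20, 0, 0]])
        rt.heavy = [np.array([[0.0, 0, 0]]), np.array([[20.0, 0, 0]])]
        ab = np.array([[3.9, 0.0, 0.0]])
        flags = F.annotate_epitopes(rt, ab, max_dist=4.0)
        assert flags.tolist() == [True, False]

    def test_distant_antibody_gives_empty_set(self, sphere):
        rt, _ = sphere
        ab = rt.ca.max(axis=0) + 100.0
        assert not F.annotate_epitopes(rt, ab[None]).any()

    def test_matches_all_pairs_oracle(self, sphere):
        rt, _ = sphere
        rng = np.random.default_rng(8)
        ab = rt.ca[rng.choice(len(rt), 5)] + rng.normal(scale=3.0, size=(5, 3))
        flags = F.annotate_epitopes(rt, ab, 4.0)
        oracle = np.array([
            any(np.linalg.norm(a - b) <= 4.0 for a in atoms for b in ab)
            for atoms in rt.heavy])
        assert np.array_equal(flags, oracle)

    def test_empty_antibody_rejected(self, sphere):
        with pytest.raises(ValueError):
            F.annotate_epitopes(sphere[0], np.empty((0, 3)))


AAINDEX_FIXTURE = """\
H TEST0101
D Synthetic uniform index (test fixture)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0
     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0
//
H TEST0202
D Synthetic ramp index with one missing value (test fixture)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.1     0.2     0.3     0.4     0.5     0.6     0.7     0.8     0.9     1.0
     1.1     1.2     1.3     1.4     1.5     1.6     1.7     1.8     1.9      NA
//
"""


@pytest.fixture(scope="module")
def table(tmp_path_factory):
    p = tmp_path_factory.mktemp("aaindex") / "aaindex1"
    p.write_text(AAINDEX_FIXTURE)
    return F.parse_aaindex1(p)


class TestAAIndex:

    def test_two_indices_twenty_values(self, table):
        assert set(table.indices) == {"TEST0101", "TEST0202"}
        assert len(table["TEST0101"]) == 20
        assert table["TEST0202"]["A"] == pytest.approx(0.1)
        assert table["TEST0202"]["L"] == pytest.approx(1.1)

    def test_na_imputed_with_mean(self, table):
        present = [v for aa, v in table["TEST0202"].items() if aa != "V"]
        assert table["TEST0202"]["V"] == pytest.approx(np.mean(present))
        assert table.imputed == {"TEST0202": ["V"]}

    def test_constant_index_gives_constant_column(self, table):
        rt = _table(np.random.default_rng(0).normal(size=(6, 3)))
        cols = F.aaindex_features(rt, table, ["TEST0101"])
        assert (cols["aaindex_TEST0101"] == 1.0).all()

    def test_polyalanine_constant_at_alanine_value(self, table):
        rt = _table(np.zeros((4, 3)) + np.arange(4)[:, None])
        cols = F.aaindex_features(rt, table, ["TEST0202"])
        assert np.allclose(cols["aaindex_TEST0202"], 0.1)


class TestLogOdds:
    def test_identical_composition_gives_zero_scores(self):
        # identical residue composition in both classes -> all scores zero
        seq = "AAAAAAAAA" + "AAAAAAAAA"
        lab = np.zeros(18, bool)
        lab[4] = True
        exp = np.zeros(18, bool)
        exp[4] = exp[13] = True  # one eligible window per class, both all-A
        model = F.fit_log_odds([seq], [lab], [exp])
        assert all(abs(v) < 1e-12 for v in model.scores.values())

    def test_epitope_only_amino_acid_scores_positive(self):
        seq = "WWWWWWWWW" + "AAAAAAAAA"
        lab = np.zeros(18, bool)
        lab[4] = True
        exp = np.zeros(18, bool)
        exp[4] = exp[13] = True  # exactly one eligible window per class
        model = F.fit_log_odds([seq], [lab], [exp])
        assert model.scores["W"] > 0
        assert np.isfinite(list(model.scores.values())).all()

    def test_hand_enumerated_counts(self):
        """Single 9-mer per class, hand-counted composition."""
        seq = "ACACACACA" + "GGGGGGGGG"
        lab = np.zeros(18, bool)
        lab[4] = True
        exp = np.zeros(18, bool)
        exp[4] = exp[13] = True
        model = F.fit_log_odds([seq], [lab], [exp], pseudocount=1.0)
        # epitope window: 5 A, 4 C; non-epitope: 9 G; totals 9 each
        expected_A = np.log2((5 + 1) / (9 + 20)) - np.log2((0 + 1) / (9 + 20))
        expected_G = np.log2((0 + 1) / (9 + 20)) - np.log2((9 + 1) / (9 + 20))
        assert model.scores["A"] == pytest.approx(expected_A)
        assert model.scores["G"] == pytest.approx(expected_G)
        scored = F.score_log_odds(model, "AG")
        assert scored[0] == pytest.approx(expected_A)
        assert scored[1] == pytest.approx(expected_G)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        lab = rng.uniform(size=60) < 0.3
        exp = np.ones(60, bool)
        m1 = F.fit_log_odds([seq], [lab], [exp])
        m2 = F.fit_log_odds([seq], [~lab], [exp])
        for aa in m1.scores:
            assert m1.scores[aa] == pytest.approx(-m2.scores[aa])

    def test_no_eligible_windows_rejected(self):
        seq = "AAAAAAAAAA"
        with pytest.raises(ValueError):
            F.fit_log_odds([seq], [np.zeros(10, bool)], [np.ones(10, bool)])


class TestBuildFeatureTable:
    def _prepared(self, sphere):
        rt, _ = sphere
        rt = rt.subset(np.arange(len(rt)))  # copy
        rt.exposed = np.ones(len(rt), bool)
        return rt

    def test_cn_plus_bfactor_gives_three_columns(self, sphere):
        rt = self._prepared(sphere)
        ds = F.build_feature_table(rt, F.FeatureOptions(
            include_hse=False, include_qse=False))
        assert ds.feature_names == ["cn", "b_ca", "b_mean"]
        assert len(ds) == len(rt)

    def test_labels_equal_epitope_flags(self, sphere):
        rt = self._prepared(sphere)
        ds = F.build_feature_table(rt)
        assert np.array_equal(ds.y, rt.epitope.astype(int))

    def test_psaia_passthrough_and_mismatch_error(self, sphere):
        import pandas as pd
        rt = self._prepared(sphere)
        psaia = pd.DataFrame({"chain": rt.chain, "resnum": rt.resnum,
                              "asa": np.arange(len(rt), dtype=float)})
        ds = F.build_feature_table(rt, F.FeatureOptions(psaia=psaia))
        assert "asa" in ds.feature_names
        with pytest.raises(ValueError):
            F.build_feature_table(rt, F.FeatureOptions(psaia=psaia.iloc[:5]))
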