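"""Feature filtering, isotope partners, alignment, matching, RT rules."""

import numpy as np
import pytest

from oxlip.annotate import (
    FilterParams,
    MatchTier,
    MS1Feature,
    MsmsSpectrum,
    align_features,
    apply_rt_rules,
    detect_isotope_partner,
    filter_features,
    match_and_verify,
    parent_label,
)
from oxlip.chem import AcylChain
from oxlip.library import LIPID_CLASSES, OxLipidCandidate

GROUPS = {f"ctl{i}": "control" for i in range(5)} | {f"salt{i}": "salt" for i in range(5)}


def feat(fid="F1", mz=752.4866, rt=6.6, inten=1000.0, partner=True, samples=None):
    samples = samples or list(GROUPS)
    return MS1Feature(fid, mz, rt, {s: inten for s in samples}, partner)


class TestFilterFeatures:
    def test_threshold_in_three_samples_of_one_group_retained(self):
        f = feat(inten=300.0, samples=["ctl0", "ctl1", "ctl2"])
        assert filter_features([f], GROUPS) == [f]

    def test_two_samples_not_enough(self):
        f = feat(inten=300.0, samples=["ctl0", "ctl1"])
        assert filter_features([f], GROUPS) == []

    def test_empty_input(self):
        assert filter_features([], GROUPS) == []

    def test_windows_and_partner(self):
        bad_mz = feat(mz=99.0)
        bad_rt = feat(rt=16.5)
        no_partner = feat(partner=False)
        ok = feat()
        out = filter_features([bad_mz, bad_rt, no_partner, ok], GROUPS)
        assert out == [ok]

    def test_planted_fixture_counts(self):
        rng = np.random.default_rng(7)
        feats = []
        for i in range(40):  # planted to pass every filter
            feats.append(feat(f"P{i}", mz=float(rng.uniform(200, 1500)), rt=5.0))
        for i in range(20):
            feats.append(feat(f"L{i}", mz=50.0))  # out of m/z window
        for i in range(20):
            feats.append(feat(f"R{i}", rt=20.0))  # out of RT window
        for i in range(10):
            feats.append(feat(f"N{i}", inten=100.0))  # below noise threshold
        for i in range(10):
            feats.append(feat(f"I{i}", partner=False))  # no isotope partner
        out = filter_features(feats, GROUPS)
        assert len(out) == 40 and all(f.feature_id.startswith("P") for f in out)

    def test_missing_group_label_raises(self):
        f = MS1Feature("X", 500.0, 5.0, {"mystery_sample": 1000.0}, True)
        with pytest.raises(KeyError, match="mystery_sample"):
            filter_features([f], GROUPS)

    def test_order_preserved(self):
        feats = [feat(f"F{i}", mz=500.0 + i) for i in range(5)]
        assert [f.feature_id for f in filter_features(feats, GROUPS)] == [
            f.feature_id for f in feats
        ]


class TestIsotopePartner:
    def test_co_eluting_pair_flagged_both_ways(self):
        a = feat("a", mz=700.0, partner=None)
        b = feat("b", mz=701.0034, partner=None)
        out = detect_isotope_partner([a, b])
        assert [f.has_isotope_partner for f in out] == [True, True]

    def test_half_dalton_apart_not_partners(self):
        a = feat("a", mz=700.0, partner=None)
        b = feat("b", mz=700.5, partner=None)
        out = detect_isotope_partner([a, b])
        assert [f.has_isotope_partner for f in out] == [False, False]

    def test_rt_separation_breaks_pair(self):
        a = feat("a", mz=700.0, rt=5.0, partner=None)
        b = feat("b", mz=701.0034, rt=6.0, partner=None)
        assert all(
            not f.has_isotope_partner for f in detect_isotope_partner([a, b])
        )

    def test_planted_pairs_flag_exactly_2k_members(self):
        rng = np.random.default_rng(11)
        feats = []
        k = 8
        for i in range(k):
            mz = float(rng.uniform(300, 1000))
            rt = float(rng.uniform(1, 10))
            feats.append(feat(f"m{i}", mz=mz, rt=rt, partner=None))
            feats.append(feat(f"i{i}", mz=mz + 1.0033548, rt=rt, partner=None))
        for i in range(20):  # singletons far from any pair, 2 Da apart
            feats.append(feat(f"s{i}", mz=1200.0 + 2.0 * i, rt=3.0, partner=None))
        out = detect_isotope_partner(feats)
        assert sum(bool(f.has_isotope_partner) for f in out) == 2 * k


class TestAlignment:
    def test_identical_tables_consensus_equals_input(self):
        table = [feat("a", mz=700.0, rt=5.0), feat("b", mz=800.0, rt=6.0)]
        out = align_features([table, table])
        assert len(out) == 2
        assert {(f.mz, f.rt) for f in out} == {(700.0, 5.0), (800.0, 6.0)}

    def test_uniform_rt_shift_with_anchor_aligns(self):
        base = [feat(f"a{i}", mz=500.0 + 10 * i, rt=rt) for i, rt in enumerate([4.0, 6.0, 8.0])]
        shifted = [
            MS1Feature(f"b{i}", f.mz, f.rt * 1.02, {"s2": 1.0}, True)
            for i, f in enumerate(base)
        ]
        # anchor observed at 6.12 in the shifted run, reference 6.0
        out = align_features([base, shifted], anchors=[None, (6.12, 6.0)])
        # middle feature aligns exactly; the others fall within the 5% window
        assert len(out) == 3

    def test_mz_beyond_tolerance_never_grouped(self):
        a = [feat("a", mz=700.00, rt=5.0)]
        b = [feat("b", mz=700.02, rt=5.0)]
        assert len(align_features([a, b])) == 2

    def test_single_table_required(self):
        with pytest.raises(ValueError):
            align_features([])


@pytest.fixture(scope="module")
def pe_candidates():
    pe = LIPID_CLASSES["PE"]
    return [
        OxLipidCandidate.build(pe, AcylChain(18, 2, 1), AcylChain(18, 3)),
        OxLipidCandidate.build(pe, AcylChain(18, 3, 1), AcylChain(18, 2)),
    ]


class TestMatchAndVerify:
    def test_self_match_at_zero_ppm(self, pe_candidates):
        cand = pe_candidates[0]
        f = feat(mz=cand.precursor_mz)
        out = match_and_verify([f], [], [cand])
        assert len(out) == 1
        assert out[0].ppm_error == 0.0
        assert out[0].tier == MatchTier.MS1_ONLY

    def test_far_off_feature_matches_nothing(self, candidates):
        f = feat(mz=752.4866 * (1 + 50e-6))
        assert match_and_verify([f], [], candidates) == []

    def test_msms_upgrades_tier(self, pe_candidates):
        cand = pe_candidates[1]  # 18:3-O/18:2: fragments 293.212 / 279.232
        f = feat(mz=cand.precursor_mz, rt=6.62)
        spec = MsmsSpectrum(cand.precursor_mz, 6.62, ((293.2117, 500.0), (279.2324, 400.0)))
        out = match_and_verify([f], [spec], [cand])
        assert out[0].tier == MatchTier.MS1_MS2
        assert out[0].n_fragments == 2

    def test_normal_fragment_alone_is_not_verification(self, pe_candidates):
        cand = pe_candidates[1]
        f = feat(mz=cand.precursor_mz, rt=6.62)
        spec = MsmsSpectrum(cand.precursor_mz, 6.62, ((279.2324, 400.0),))
        out = match_and_verify([f], [spec], [cand])
        assert out[0].tier == MatchTier.MS1_ONLY

    def test_rt_window_gates_spectra(self, pe_candidates):
        cand = pe_candidates[1]
        f = feat(mz=cand.precursor_mz, rt=6.62)
        spec = MsmsSpectrum(cand.precursor_mz, 7.5, ((293.2117, 500.0),))
        out = match_and_verify([f], [spec], [cand])
        assert out[0].tier == MatchTier.MS1_ONLY

    def test_planted_vs_decoys(self, candidates):
        rng = np.random.default_rng(3)
        chosen = [candidates[int(i)] for i in rng.choice(len(candidates), 20, replace=False)]
        feats = []
        for i, c in enumerate(chosen):
            eps = float(rng.uniform(-4.5, 4.5))
            feats.append(feat(f"P{i}", mz=c.precursor_mz * (1 + eps * 1e-6)))
        for i, c in enumerate(chosen):
            sign = 1 if i % 2 else -1
            feats.append(feat(f"D{i}", mz=c.precursor_mz * (1 + sign * 25e-6)))
        out = match_and_verify(feats, [], candidates)
        matched = {m.feature.feature_id for m in out}
        assert all(fid.startswith("P") for fid in matched)
        assert len({fid for fid in matched}) == 20

    def test_tolerance_monotone(self, candidates):
        rng = np.random.default_rng(5)
        feats = [
            feat(f"F{i}", mz=c.precursor_mz * (1 + float(rng.normal(0, 3)) * 1e-6))
            for i, c in enumerate(candidates[:40])
        ]
        wide = match_and_verify(feats, [], candidates, ms1_tol_ppm=5)
        narrow = match_and_verify(feats, [], candidates, ms1_tol_ppm=2)
        wide_keys = {(m.feature.feature_id, m.candidate.chain_composition) for m in wide}
        narrow_keys = {(m.feature.feature_id, m.candidate.chain_composition) for m in narrow}
        assert narrow_keys <= wide_keys

    def test_deterministic_ranking(self, candidates):
        f = feat(mz=752.4866, rt=6.6)
        a = match_and_verify([f], [], candidates)
        b = match_and_verify([f], [], candidates)
        assert [(m.candidate.label, m.candidate.chain_composition) for m in a] == [
            (m.candidate.label, m.candidate.chain_composition) for m in b
        ]


from conftest import brute_force_rule_b_violations  # noqa: E402


@pytest.fixture(scope="module")
def pe_by_label(candidates):
    out = {}
    for c in candidates:
        if c.lipid_class.name == "PE" and c.total_extra_oxygens == 1:
            out.setdefault(c.label, c)
    return out


class TestRtRules:
    def _matches_for(self, rt_by_label, pe_cands_by_label):
        feats_matches = []
        for label, rt in rt_by_label.items():
            cand = pe_cands_by_label[label]
            f = feat(label, mz=cand.precursor_mz, rt=rt)
            spec = MsmsSpectrum(cand.precursor_mz, rt, tuple((mz, 100.0) for _, mz in cand.products))
            feats_matches += match_and_verify([f], [spec], [cand])
        return feats_matches

    def test_rule_a_pass_and_fail(self, pe_by_label):
        cand = pe_by_label["PE(36:5)-O"]
        f = feat(mz=cand.precursor_mz, rt=6.62)
        m = match_and_verify([f], [], [cand])
        ok = apply_rt_rules(m, parent_rts={"PE(36:5)": 7.9})
        assert all(o.passed for o in ok[0].rt_checks if o.rule == "A")
        bad = apply_rt_rules(m, parent_rts={"PE(36:5)": 6.0})
        assert any(not o.passed for o in bad[0].rt_checks if o.rule == "A")

    def test_rule_b_reference_elution_order(self, pe_by_label):
        # curated RTs: more double bonds at equal carbons elute earlier
        rts = {"PE(36:4)-O": 7.3, "PE(36:5)-O": 6.62, "PE(36:6)-O": 5.98}
        matches = self._matches_for(rts, pe_by_label)
        checked = apply_rt_rules(matches)
        assert all(o.passed for m in checked for o in m.rt_checks)

    def test_rule_b_flags_inversion_without_dropping(self, pe_by_label):
        rts = {"PE(36:4)-O": 6.0, "PE(36:5)-O": 6.62}  # inverted
        matches = self._matches_for(rts, pe_by_label)
        checked = apply_rt_rules(matches)
        assert len(checked) == len(matches)  # flagged, not dropped
        flagged = {m.candidate.label for m in checked if any(not o.passed for o in m.rt_checks)}
        assert flagged == {"PE(36:4)-O", "PE(36:5)-O"}
        assert all(m.tier == MatchTier.MS1_MS2 for m in checked)

    def test_permuted_rts_match_brute_force_oracle(self, pe_by_label):
        labels = sorted(pe_by_label)
        rng = np.random.default_rng(17)
        base_rts = {lbl: 4.0 + 0.5 * i for i, lbl in enumerate(labels)}
        for trial in range(10):
            perm = rng.permutation(list(base_rts.values()))
            rts = dict(zip(labels, map(float, perm)))
            matches = self._matches_for(rts, pe_by_label)
            checked = apply_rt_rules(matches)
            flagged = {
                m.candidate.label
                for m in checked
                if any(o.rule == "B" and not o.passed for o in m.rt_checks)
            }
            oracle = brute_force_rule_b_violations(
                [
                    (
                        lbl,
                        "PE",
                        1,
                        c.chain1.carbons + c.chain2.carbons,
                        c.chain1.double_bonds + c.chain2.double_bonds,
                        rts[lbl],
                    )
                    for lbl, c in pe_by_label.items()
                ]
            )
            assert flagged == oracle

    def test_tier_upgrade_only_when_clean(self, pe_by_label):
        rts = {"PE(36:4)-O": 7.3, "PE(36:5)-O": 6.62}
        matches = self._matches_for(rts, pe_by_label)
        checked = apply_rt_rules(matches, parent_rts={"PE(36:4)": 7.9, "PE(36:5)": 7.9})
        assert all(m.tier == MatchTier.MS1_MS2_RT for m in checked)


def test_parent_label():
    assert parent_label("PE(36:5)-O") == "PE(36:5)"
    assert parent_label("PS(34:3)-2O") == "PS(34:3)"
    assert parent_label("PC(34:1)") == "PC(34:1)"
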