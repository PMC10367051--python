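"""Profile assembly, stitching, barriers and the rate-determining step."""

import warnings

import numpy as np
import pytest

from oxakin import reference as ref
from oxakin.energy_model import ProtocolTag
from oxakin.profiles import (
    Barrier, ProfilePoint, ReactionProfile, StitchEvent, barrier_between,
    build_profile, elementary_barriers, export_diagram, profile_to_frame,
    rate_determining_step, stitch_profiles,
)
from oxakin.records import (
    EnergyComponents, FrequencySet, StationaryPointRecord, ValidationError,
    MINIMUM, TRANSITION_STATE,
)
from oxakin.synthetic import GeneratorSpec, make_profile_records


class TestBuildProfile:
    def test_synthetic_records_reproduce_tabulated_step1(self):
        records = make_profile_records(GeneratorSpec(seed=7))
        prof = build_profile(records, ProtocolTag.G_TPSS, "MC_S1")
        for label, expected in zip(ref.PROFILE_LABELS,
                                   ref.COMPOSITE_PROFILES["G_TPSS"]):
            assert prof.g(label) == pytest.approx(expected, abs=0.05)

    def test_single_record_profile(self):
        records = [StationaryPointRecord(
            "MC_S1", MINIMUM, EnergyComponents(single_point={"E_TPSS": -3.0}))]
        prof = build_profile(records, ProtocolTag.E_TPSS, "MC_S1")
        assert prof.labels == ("MC_S1",) and prof.g("MC_S1") == 0.0

    def test_gauge_invariance(self):
        records = make_profile_records(GeneratorSpec(seed=2))
        shifted = [
            StationaryPointRecord(
                r.label, r.role,
                EnergyComponents(single_point={
                    k: v + 7.3 for k, v in r.energies.single_point.items()}),
                frequencies=r.frequencies,
            )
            for r in records
        ]
        p0 = build_profile(records, ProtocolTag.G_TPSS, "MC_S1")
        p1 = build_profile(shifted, ProtocolTag.G_TPSS, "MC_S1")
        for a, b in zip(p0.points, p1.points):
            assert a.g == pytest.approx(b.g, abs=1e-9)

    def test_consecutive_transition_states_rejected(self):
        pts = (
            ProfilePoint("A", MINIMUM, 0.0),
            ProfilePoint("B", TRANSITION_STATE, 5.0),
            ProfilePoint("C", TRANSITION_STATE, 6.0),
            ProfilePoint("D", MINIMUM, -1.0),
        )
        with pytest.raises(ValidationError, match="consecutive"):
            ReactionProfile(pts, "A")

    def test_missing_reference_rejected(self):
        records = [StationaryPointRecord(
            "MC_S1", MINIMUM, EnergyComponents(single_point={"E_TPSS": 0.0}))]
        with pytest.raises(ValidationError, match="reference"):
            build_profile(records, ProtocolTag.E_TPSS, "nope")


class TestStitching:
    def test_water_link_places_second_step_on_absolute_scale(
            self, step_profiles):
        p1, p2 = step_profiles("G_TPSS")
        link = StitchEvent("P_S1", "MC_S2gm", ref.WATER_BINDING_DG,
                           species="water association")
        full = stitch_profiles(p1, p2, link)
        assert full.scale == "absolute"
        assert full.g("MC_S2gm") == pytest.approx(-16.0, abs=1e-9)
        # the remainder of the tabulated column is reproduced
        for label, expected in zip(ref.PROFILE_LABELS,
                                   ref.COMPOSITE_PROFILES["G_TPSS"]):
            assert full.g(label) == pytest.approx(expected, abs=1e-9)

    def test_difluoroacetate_dissociation_gives_final_product(
            self, step_profiles, full_profile):
        full = full_profile("G_TPSS")
        p_fin = ReactionProfile.from_values(["P_FIN"], [MINIMUM], [0.0])
        link = StitchEvent("P_S2", "P_FIN",
                           ref.DIFLUOROACETATE_DISSOCIATION_DG,
                           species="difluoroacetate dissociation")
        stitched = stitch_profiles(full, p_fin, link)
        assert stitched.g("P_FIN") == pytest.approx(-20.3, abs=1e-9)

    def test_zero_link_is_concatenation(self, step_profiles):
        p1, p2 = step_profiles("G_TPSS")
        full = stitch_profiles(p1, p2, StitchEvent("P_S1", "MC_S2gm", 0.0))
        assert full.g("MC_S2gm") == pytest.approx(full.g("P_S1"), abs=1e-12)

    def test_standard_state_term_optional(self, step_profiles):
        p1, p2 = step_profiles("G_TPSS")
        link = StitchEvent("P_S1", "MC_S2gm", -1.0, delta_n=-1)
        plain = stitch_profiles(p1, p2, link)
        with_ss = stitch_profiles(p1, p2, link, apply_standard_state=True)
        assert with_ss.g("MC_S2gm") == pytest.approx(
            plain.g("MC_S2gm") - 1.89, abs=0.01)

    def test_associative(self, step_profiles):
        p1, p2 = step_profiles("G_TPSS")
        p3 = ReactionProfile.from_values(["P_FIN"], [MINIMUM], [0.0])
        l12 = StitchEvent("P_S1", "MC_S2gm", ref.WATER_BINDING_DG)
        l23 = StitchEvent("P_S2", "P_FIN",
                          ref.DIFLUOROACETATE_DISSOCIATION_DG)
        left = stitch_profiles(stitch_profiles(p1, p2, l12), p3, l23)
        right = stitch_profiles(p1, stitch_profiles(p2, p3, l23), l12)
        for a, b in zip(left.points, right.points):
            assert a.g == pytest.approx(b.g, abs=1e-9)

    def test_bad_link_endpoints(self, step_profiles):
        p1, p2 = step_profiles("G_TPSS")
        with pytest.raises(ValidationError):
            stitch_profiles(p1, p2, StitchEvent("TI_S1", "MC_S2gm", -1.0))
        with pytest.raises(ValidationError):
            stitch_profiles(p1, p2, StitchEvent("P_S1", "TS1_S2", -1.0))


class TestBarriers:
    def test_step1_barriers_match_printed_arithmetic(self, full_profile):
        barriers = elementary_barriers(full_profile("G_TPSS"))
        lookup = {b.ts: b for b in barriers}
        assert lookup["TS1_S1"] == Barrier("MC_S1", "TS1_S1",
                                           pytest.approx(4.4, abs=1e-9))
        assert lookup["TS2_S1"].from_minimum == "TI_S1"
        assert lookup["TS2_S1"].delta_g_act == pytest.approx(21.0, abs=1e-9)

    def test_step2_barriers_use_nearest_preceding_minimum(self, full_profile):
        prof = full_profile("G_TPSS")
        lookup = {b.ts: b for b in elementary_barriers(prof)}
        # nearest preceding minimum of TS1_S2 is the rearranged complex
        assert lookup["TS1_S2"].from_minimum == "MC_S2p"
        assert lookup["TS1_S2"].delta_g_act == pytest.approx(5.9, abs=1e-9)
        assert lookup["TS2_S2"].from_minimum == "TI_S2"
        assert lookup["TS2_S2"].delta_g_act == pytest.approx(9.3, abs=1e-9)
        # the alternative reference from the global-minimum water complex
        assert barrier_between(prof, "MC_S2gm", "TS1_S2") == pytest.approx(
            18.2, abs=1e-9)

    def test_no_ts_profile_has_no_barriers(self):
        prof = ReactionProfile.from_values(["A"], [MINIMUM], [0.0])
        assert elementary_barriers(prof) == []

    def test_ts_below_minimum_warns(self):
        prof = ReactionProfile.from_values(
            ["A", "B", "C"], [MINIMUM, TRANSITION_STATE, MINIMUM],
            [0.0, -1.0, -5.0])
        with pytest.warns(UserWarning, match="below"):
            elementary_barriers(prof)

    def test_invariant_under_constant_shift(self, full_profile):
        prof = full_profile("G_TPSS")
        shifted = prof.shifted(13.7, scale="absolute")
        b0 = elementary_barriers(prof)
        b1 = elementary_barriers(shifted)
        assert all(x.delta_g_act == pytest.approx(y.delta_g_act, abs=1e-9)
                   for x, y in zip(b0, b1))


class TestRateDeterminingStep:
    def test_tpss_rds(self, full_profile):
        rds = rate_determining_step(full_profile("G_TPSS"))
        assert (rds.from_minimum, rds.ts) == ("TI_S1", "TS2_S1")
        assert rds.delta_g_act == pytest.approx(21.0, abs=1e-9)

    def test_b3lyp_rds(self, full_profile):
        rds = rate_determining_step(full_profile("G_B3LYP"))
        assert (rds.from_minimum, rds.ts) == ("TI_S1", "TS2_S1")
        assert rds.delta_g_act == pytest.approx(21.6, abs=1e-9)

    def test_tie_returns_first_and_reports_both(self):
        prof = ReactionProfile.from_values(
            ["A", "T1", "B", "T2", "C"],
            [MINIMUM, TRANSITION_STATE, MINIMUM, TRANSITION_STATE, MINIMUM],
            [0.0, 10.0, -5.0, 5.0, -8.0])
        rds = rate_determining_step(prof)
        assert rds.ts == "T1" and len(rds.ties) == 2

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_seg = rng.integers(1, 4)
            labels, roles, values = [], [], []
            idx = 0
            for _s in range(n_seg):
                n_ts = int(rng.integers(1, 4))
                for j in range(2 * n_ts + 1):
                    labels.append(f"p{idx}")
                    roles.append(MINIMUM if j % 2 == 0 else TRANSITION_STATE)
                    values.append(float(rng.normal(0.0, 10.0)))
                    idx += 1
            values[0] = 0.0
            prof = ReactionProfile.from_values(labels, roles, values)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rds = rate_determining_step(prof)
                # independent oracle: naive backward scan per TS
                best = None
                for i, r in enumerate(roles):
                    if r != TRANSITION_STATE:
                        continue
                    j = i - 1
                    while roles[j] != MINIMUM:
                        j -= 1
                    dg = values[i] - values[j]
                    if best is None or dg > best[2]:
                        best = (labels[j], labels[i], dg)
            assert (rds.from_minimum, rds.ts) == best[:2]
            assert rds.delta_g_act == pytest.approx(best[2], abs=1e-9)


class TestReReference:
    def test_re_reference_to_rearranged_complex(self, full_profile):
        prof = full_profile("E_TPSS")
        step2 = prof.segment("MC_S2p", "P_S2")
        assert step2.g("MC_S2p") == 0.0
        assert step2.g("TS1_S2") == pytest.approx(6.0, abs=1e-9)
        assert step2.g("TS2_S2") == pytest.approx(12.1, abs=1e-9)

    def test_re_reference_requires_minimum(self, full_profile):
        with pytest.raises(ValidationError):
            full_profile("G_TPSS").re_reference("TS1_S1")


class TestExportDiagram:
    def test_round_trip_and_determinism(self, tmp_path, full_profile):
        prof = full_profile("G_TPSS")
        png = tmp_path / "ladder.png"
        csv = tmp_path / "ladder.csv"
        export_diagram(prof, png, csv)
        assert png.exists()
        df = profile_to_frame(prof)
        import pandas as pd
        back = pd.read_csv(csv)
        np.testing.assert_allclose(back["g_kcal_mol"], df["g_kcal_mol"],
                                   atol=0.05)
        first = csv.read_bytes()
        export_diagram(prof, png, csv)
        assert csv.read_bytes() == first

    def test_single_point_flat(self, tmp_path):
        prof = ReactionProfile.from_values(["A"], [MINIMUM], [0.0])
        export_diagram(prof, tmp_path / "one.png", tmp_path / "one.csv")
        import pandas as pd
        back = pd.read_csv(tmp_path / "one.csv")
        assert len(back) == 1 and back["g_kcal_mol"][0] == 0.0
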