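import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from waspmorph.landmark_io import LandmarkConfiguration
from waspmorph.measurements import (
    RATIO_NAMES,
    HeadMeasurements,
    compute_ratios,
    fe_fep_per_side,
    group_ratio_summary,
    measures_from_landmarks,
)
from waspmorph.synthetic import make_templates


def _measures(**over):
    base = dict(specimen_id="w", MHW=2.0, HL=1.0, OIO=0.3, MIO=0.5, AIO=0.2, FE=0.4, FEP=0.1)
    base.update(over)
    return HeadMeasurements(**base)


class TestComputeRatios:
    def test_direct_quotient(self):
        assert compute_ratios(_measures(MHW=2.0, HL=1.0)).MHW_HL == pytest.approx(2.0)

    def test_all_equal_measures_give_unit_ratios(self):
        m = _measures(MHW=3.0, HL=3.0, OIO=3.0, MIO=3.0, AIO=3.0, FE=3.0, FEP=3.0)
        r = compute_ratios(m)
        assert all(getattr(r, name) == pytest.approx(1.0) for name in RATIO_NAMES)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        vals=st.lists(st.floats(min_value=0.01, max_value=100.0, allow_nan=False), min_size=7, max_size=7)
    )
    def test_matches_elementwise_division_oracle(self, vals):
        mhw, hl, oio, fe, fep = vals[0], vals[1], vals[2], vals[5], vals[6]
        mio = max(vals[3], vals[4])
        aio = min(vals[3], vals[4])
        m = _measures(MHW=mhw, HL=hl, OIO=oio, MIO=mio, AIO=aio, FE=fe, FEP=fep)
        r = compute_ratios(m)
        # independent per-field division oracle
        assert r.MHW_HL == pytest.approx(mhw / hl, rel=1e-12)
        assert r.OIO_HL == pytest.approx(oio / hl, rel=1e-12)
        assert r.MIO_HL == pytest.approx(mio / hl, rel=1e-12)
        assert r.AIO_HL == pytest.approx(aio / hl, rel=1e-12)
        assert r.FEP_FE == pytest.approx(fep / fe, rel=1e-12)

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError, match="AIO"):
            _measures(AIO=0.6, MIO=0.5)
        with pytest.raises(ValueError, match="positive"):
            _measures(HL=0.0)


def _template_config(key=("Nv", "male")):
    t = make_templates()[key]
    return LandmarkConfiguration("tmpl", t.coords), t.aux


class TestMeasuresFromLandmarks:
    def test_fep_axis_aligned(self, scheme):
        # FE segment on the y-axis, cheek arc 3 units off it -> FEP = 3
        coords = make_templates()[("Nv", "male")].coords.copy()
        coords[scheme.index("eye-bottom-L")] = (0.0, 0.0)
        coords[scheme.index("mandible-center")] = (0.0, -4.0)
        coords[scheme.index("cheek-arc-L")] = (3.0, -2.0)
        c = LandmarkConfiguration("w", coords)
        per_side = fe_fep_per_side(c)
        assert per_side["L"] == (pytest.approx(4.0), pytest.approx(3.0))

    def test_mio_euclidean_distance(self, scheme):
        coords = make_templates()[("Nv", "male")].coords.copy()
        coords[scheme.index("mio-L")] = (-5.0, 0.0)
        coords[scheme.index("mio-R")] = (5.0, 0.0)
        c = LandmarkConfiguration("w", coords)
        m = measures_from_landmarks(c, aux=make_templates()[("Nv", "male")].aux)
        assert m.MIO == pytest.approx(10.0)

    def test_matches_geometry_oracle(self, rng, scheme):
        base, aux = _template_config()
        coords = base.coords + rng.normal(0, 0.01, size=(16, 2))
        c = LandmarkConfiguration("w", coords)
        m = measures_from_landmarks(c, aux=aux)

        # test-only explicit distance / projection formulas
        def d(p, q):
            return float(np.hypot(p[0] - q[0], p[1] - q[1]))

        lm = {name: coords[scheme.index(name)] for name in scheme.names}
        assert m.OIO == pytest.approx(d(lm["lateral-ocellus-L"], lm["lateral-ocellus-R"]))
        assert m.MIO == pytest.approx(d(lm["mio-L"], lm["mio-R"]))
        assert m.AIO == pytest.approx(d(lm["antennal-socket-L"], lm["antennal-socket-R"]))
        assert m.MHW == pytest.approx(d(aux["head_left"], aux["head_right"]))
        assert m.HL == pytest.approx(d(aux["head_top"], aux["head_bottom"]))
        fes, feps = [], []
        for side in ("L", "R"):
            a, b = lm[f"eye-bottom-{side}"], lm["mandible-center"]
            p = lm[f"cheek-arc-{side}"]
            fes.append(d(a, b))
            # area of parallelogram / base length
            area2 = abs((b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0]))
            feps.append(area2 / d(a, b))
        assert m.FE == pytest.approx(np.mean(fes))
        assert m.FEP == pytest.approx(np.mean(feps))

    def test_missing_aux_lists_measures(self):
        c, _ = _template_config()
        with pytest.raises(ValueError, match="MHW.*HL"):
            measures_from_landmarks(c, aux={})

    def test_oio_proxy_flag_and_aux_pathway(self):
        c, aux = _template_config()
        assert measures_from_landmarks(c, aux=aux).oio_is_proxy
        aux2 = dict(aux, oio_left=(-0.2, 0.88), oio_right=(0.2, 0.88))
        m = measures_from_landmarks(c, aux=aux2)
        assert not m.oio_is_proxy
        assert m.OIO == pytest.approx(0.4)


class TestInvariances:
    def test_scale_invariance_of_ratios(self):
        c, aux = _template_config()
        r1 = compute_ratios(measures_from_landmarks(c, aux=aux))
        k = 3.7
        c2 = c.with_coords(c.coords * k)
        aux2 = {name: np.asarray(p) * k for name, p in aux.items()}
        r2 = compute_ratios(measures_from_landmarks(c2, aux=aux2))
        for name in RATIO_NAMES:
            assert getattr(r1, name) == pytest.approx(getattr(r2, name), abs=1e-9)

    def test_rotation_translation_invariance_of_measures(self):
        c, aux = _template_config()
        m1 = measures_from_landmarks(c, aux=aux)
        theta, shift = 0.7, np.array([3.0, -2.0])
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        c2 = c.with_coords(c.coords @ rot.T + shift)
        aux2 = {name: rot @ np.asarray(p) + shift for name, p in aux.items()}
        m2 = measures_from_landmarks(c2, aux=aux2)
        for name in ("MHW", "HL", "OIO", "MIO", "AIO", "FE", "FEP"):
            assert getattr(m1, name) == pytest.approx(getattr(m2, name), abs=1e-9)

    def test_mirror_exchanges_per_side_fe_fep(self, rng):
        base, _ = _template_config()
        coords = base.coords + rng.normal(0, 0.02, size=(16, 2))
        c = LandmarkConfiguration("w", coords)
        mirrored_coords = coords.copy()
        mirrored_coords[:, 0] = -mirrored_coords[:, 0]
        # mirror without relabeling: the geometric sides swap roles
        scheme = c.scheme
        swapped = mirrored_coords.copy()
        for left, right in scheme.paired:
            i, j = scheme.index(left), scheme.index(right)
            swapped[[i, j]] = mirrored_coords[[j, i]]
        c_mirror = LandmarkConfiguration("w", swapped)
        a = fe_fep_per_side(c)
        b = fe_fep_per_side(c_mirror)
        assert a["L"] == pytest.approx(b["R"], abs=1e-12)
        assert a["R"] == pytest.approx(b["L"], abs=1e-12)


class TestGroupSummary:
    def test_constant_group(self):
        rows = [
            compute_ratios(_measures(specimen_id=f"w{i}", group="Nv", sex="male"))
            for i in range(3)
        ]
        table = group_ratio_summary(rows)
        assert table.loc[0, "n"] == 3
        assert table.loc[0, "MHW_HL_sd"] == pytest.approx(0.0)

    def test_known_mean_sd(self):
        rows = [
            compute_ratios(_measures(specimen_id=f"w{i}", group="g", sex="m", MHW=v, HL=1.0))
            for i, v in enumerate((1.0, 2.0, 3.0))
        ]
        table = group_ratio_summary(rows)
        assert table.loc[0, "MHW_HL_mean"] == pytest.approx(2.0)
        assert table.loc[0, "MHW_HL_sd"] == pytest.approx(1.0)  # unbiased, n-1

    def test_matches_bruteforce_mean_sd_oracle(self, rng):
        vals = rng.uniform(0.5, 1.5, size=8)
        rows = [
            compute_ratios(_measures(specimen_id=f"w{i}", group="g", sex="m", MHW=v, HL=1.0))
            for i, v in enumerate(vals)
        ]
        table = group_ratio_summary(rows)
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert table.loc[0, "MHW_HL_mean"] == pytest.approx(mean)
        assert table.loc[0, "MHW_HL_sd"] == pytest.approx(sd)

    def test_singleton_group_sd_undefined_and_empty_errors(self):
        rows = [compute_ratios(_measures(group="solo", sex="m"))]
        table = group_ratio_summary(rows)
        assert np.isnan(table.loc[0, "MHW_HL_sd"])
        with pytest.raises(ValueError):
            group_ratio_summary([])
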