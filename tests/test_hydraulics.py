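"""Cross-section geometry and the shell hydraulic model."""

import numpy as np
import pytest

from rootclines.errors import GeometryError
from rootclines.hydraulics import (
    AnatomyParams,
    HydraulicParams,
    axial_conductance,
    build_cross_section,
    cluster_composite,
    radial_conductance_network,
    radial_properties,
    random_valid_params,
)

MM = 1e-3


def base_params(**kw):
    d = dict(rxsa=1.2, tsa_rxsa=0.2, ccfn=8, ccs=4e-4, aa=0.0, nmv=4, md=0.06)
    d.update(kw)
    return AnatomyParams(**d)


class TestGeometry:
    def test_outer_radius_from_area(self):
        sec = build_cross_section(base_params(rxsa=1.0))
        assert sec.outer_radius == pytest.approx(np.sqrt(1.0 / np.pi), abs=1e-9)

    def test_no_aerenchyma_means_zero_fractions(self):
        sec = build_cross_section(base_params(aa=0.0))
        assert all(l.aerenchyma_frac == 0 for l in sec.layers)

    def test_area_round_trip_on_random_draws(self, rng):
        for _ in range(100):
            p = random_valid_params(rng)
            sec = build_cross_section(p)
            areas = sec.recomputed_areas()
            assert abs(areas["TSA"] - p.tsa) <= 0.1 * p.tsa
            assert abs(areas["TCA"] - p.tca) <= 0.1 * p.tca
            if p.aa > 1e-6:
                assert abs(areas["AA"] - p.aa) <= 0.1 * p.aa
            assert abs(areas["RXSA"] - p.rxsa) <= 1e-9

    def test_layer_radii_decrease_inward(self):
        sec = build_cross_section(base_params())
        r = [l.r_outer for l in sec.layers]
        assert all(b < a for a, b in zip(r, r[1:]))
        kinds = [l.kind for l in sec.layers]
        assert kinds[0] == "epidermis" and "endodermis" in kinds

    def test_too_many_files_for_thin_cortex(self):
        with pytest.raises(GeometryError, match="cell files"):
            build_cross_section(base_params(rxsa=0.05, ccfn=16))

    def test_overlapping_vessels_rejected(self):
        with pytest.raises(GeometryError, match="overlap"):
            build_cross_section(base_params(nmv=20, md=0.09))

    def test_aerenchyma_beyond_cortex_rejected(self):
        with pytest.raises(GeometryError, match="aerenchyma"):
            build_cross_section(base_params(aa=5.0))


class TestAxial:
    def test_single_vessel_closed_form(self):
        sec = build_cross_section(base_params(nmv=1, md=0.1))
        hyd = HydraulicParams(mu=1.0e-9)
        expect = np.pi * (0.1 * MM) ** 4 / (128 * 1.0e-9)
        assert axial_conductance(sec, hyd) == pytest.approx(expect, rel=1e-12)

    def test_linear_in_vessel_count(self):
        hyd = HydraulicParams()
        k1 = axial_conductance(build_cross_section(base_params(nmv=3)), hyd)
        k2 = axial_conductance(build_cross_section(base_params(nmv=6)), hyd)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_fourth_power_of_diameter(self):
        hyd = HydraulicParams()
        k1 = axial_conductance(build_cross_section(base_params(nmv=1, md=0.04)), hyd)
        k2 = axial_conductance(build_cross_section(base_params(nmv=1, md=0.08)), hyd)
        assert k2 == pytest.approx(16 * k1, rel=1e-12)

    def test_no_vessels_zero(self):
        sec = build_cross_section(base_params(nmv=0, md=0.0))
        assert axial_conductance(sec, HydraulicParams()) == 0.0


class TestRadial:
    def test_single_layer_formula_collapse(self):
        # one membrane-only layer: Kr = pi r L Lp
        from rootclines.hydraulics import CrossSection, Layer
        lay = Layer("only", "cortex", 0.5, 0.3, 10)
        sec = CrossSection(layers=[lay], vessel_diameters=[],
                           vessel_circle_radius=0.1, segment_length=0.01)
        hyd = HydraulicParams(k_wall=0.0)
        props = radial_properties(sec, hyd)
        expect = np.pi * lay.r_mid * MM * 0.01 * hyd.lp
        assert props.Kr == pytest.approx(expect, rel=1e-12)

    def test_network_oracle_agreement(self, rng):
        for i in range(30):
            p = random_valid_params(rng)
            sec = build_cross_section(p)
            hyd = HydraulicParams(casparian=bool(i % 2))
            a = radial_properties(sec, hyd).Kr
            b = radial_conductance_network(sec, hyd)
            assert abs(a - b) <= 1e-8 * a

    def test_casparian_removal_increases_kr(self, rng):
        for _ in range(10):
            p = random_valid_params(rng)
            sec = build_cross_section(p)
            on = radial_properties(sec, HydraulicParams(casparian=True)).Kr
            off = radial_properties(sec, HydraulicParams(casparian=False)).Kr
            assert off > on

    def test_kr_monotone_in_membrane_and_wall_conductivity(self):
        sec = build_cross_section(base_params())
        krs = [radial_properties(sec, HydraulicParams(lp=lp)).Kr
               for lp in (1e-7, 3e-7, 6e-7, 1e-6)]
        assert np.all(np.diff(krs) > 0)
        krs = [radial_properties(sec, HydraulicParams(k_wall=kw)).Kr
               for kw in (1e-12, 1e-11, 5e-11)]
        assert np.all(np.diff(krs) > 0)

    def test_kr_decreases_with_file_number(self):
        hyd = HydraulicParams()
        vals = [radial_properties(build_cross_section(base_params(ccfn=c)), hyd).kr
                for c in (4, 6, 8, 10, 12)]
        assert np.all(np.diff(vals) < 0)

    def test_units_round_trip(self, rng):
        p = random_valid_params(rng)
        sec = build_cross_section(p)
        props = radial_properties(sec, HydraulicParams())
        surface = 2 * np.pi * sec.outer_radius * MM * sec.segment_length
        assert props.Kr == pytest.approx(props.kr * surface, rel=1e-9)

    def test_aerenchyma_obstruction_reduces_kr(self):
        hyd = HydraulicParams()
        k0 = radial_properties(build_cross_section(base_params(aa=0.0)), hyd).kr
        k1 = radial_properties(build_cross_section(base_params(aa=0.3)), hyd).kr
        assert k1 < k0


class TestComposites:
    def _proj(self, rows):
        import pandas as pd
        return pd.DataFrame(rows).set_index("accession")

    def test_identical_members_equal_composite(self):
        import pandas as pd
        row = {"TSA.RXSA": 0.2, "CCFN": 8, "CCS": 4e-4, "AA": 0.05,
               "NMV": 5, "MD": 0.06}
        proj = self._proj([{"accession": f"a{i}", **row} for i in range(4)])
        labels = pd.Series([1, 1, 2, 2], index=proj.index)
        out = cluster_composite(proj, labels, training_means={"RXSA": 1.2})
        assert out.loc[0, "Kx"] == pytest.approx(out.loc[1, "Kx"], rel=1e-12)
        single = cluster_composite(proj.iloc[:2], labels.iloc[:2],
                                   training_means={"RXSA": 1.2})
        assert single.loc[0, "Kx"] == pytest.approx(out.loc[0, "Kx"], rel=1e-12)

    def test_planted_ordering_recovered(self, rng):
        import pandas as pd
        lo = [{"accession": f"lo{i}", "TSA.RXSA": 0.2, "CCFN": 8, "CCS": 4e-4,
               "AA": 0.02, "NMV": 3 + int(rng.integers(0, 2)), "MD": 0.04}
              for i in range(5)]
        hi = [{"accession": f"hi{i}", "TSA.RXSA": 0.2, "CCFN": 8, "CCS": 4e-4,
               "AA": 0.02, "NMV": 8 + int(rng.integers(0, 2)), "MD": 0.08}
              for i in range(5)]
        proj = self._proj(lo + hi)
        labels = pd.Series([1] * 5 + [2] * 5, index=proj.index)
        out = cluster_composite(proj, labels, training_means={"RXSA": 1.2})
        kx = out.set_index("cluster")["Kx"]
        assert kx[2] > kx[1]

    def test_median_invariant_to_member_permutation(self, rng):
        import pandas as pd
        rows = [{"accession": f"m{i}", "TSA.RXSA": float(rng.uniform(0.15, 0.25)),
                 "CCFN": int(rng.integers(6, 10)), "CCS": 4e-4, "AA": 0.02,
                 "NMV": int(rng.integers(3, 8)), "MD": 0.05} for i in range(9)]
        proj = self._proj(rows)
        labels = pd.Series([1] * 9, index=proj.index)
        out1 = cluster_composite(proj, labels, training_means={"RXSA": 1.2})
        perm = proj.sample(frac=1.0, random_state=2)
        out2 = cluster_composite(perm, labels.loc[perm.index],
                                 training_means={"RXSA": 1.2})
        assert out1.loc[0, "Kx"] == pytest.approx(out2.loc[0, "Kx"], rel=1e-12)
        assert out1.loc[0, "kr"] == pytest.approx(out2.loc[0, "kr"], rel=1e-12)

    def test_small_cluster_flagged(self):
        import pandas as pd
        row = {"TSA.RXSA": 0.2, "CCFN": 8, "CCS": 4e-4, "AA": 0.0,
               "NMV": 4, "MD": 0.05}
        proj = self._proj([{"accession": f"a{i}", **row} for i in range(4)])
        labels = pd.Series([1, 1, 1, 2], index=proj.index)
        out = cluster_composite(proj, labels, training_means={"RXSA": 1.2})
        assert bool(out.set_index("cluster").loc[2, "small_cluster"])
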