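"""Simplified digital root cross-sections and their hydraulic properties.

A root cross-section is reconstructed from standard anatomical parameters
(cross-section area RXSA, stele:root ratio, cortical file number and cell
size, aerenchyma area, metaxylem vessel count and diameter) as a stack of
concentric layers: epidermis, CCFN cortical rings, endodermis, pericycle and
stele ground tissue, with metaxylem vessels placed on a circle inside the
stele.

Hydraulics are estimated on an axisymmetric shell simplification of explicit
cell-network models:

* axial conductance ``Kx`` is the Hagen-Poiseuille sum over metaxylem
  vessels, ``Kx = sum_v pi d_v^4 / (128 mu)``;
* radial conductance ``Kr`` composes, in series across layers, the parallel
  pair of a cell-to-cell path (two membranes per layer, conductance
  ``2 pi r L Lp / 2``) and an apoplastic wall path
  (``2 pi r L k_wall / t``).  A Casparian strip blocks the apoplastic path
  at the endodermis; aerenchyma lacunae obstruct a circumferential fraction
  of their ring.  ``kr = Kr / (2 pi r_outer L)`` is the conductivity per
  root surface area.

The shell model preserves the qualitative structure of the explicit
cell-scale models (membrane vs wall paths, Casparian barrier, aerenchyma
obstruction) while remaining fully testable against an independent Kirchhoff
network solution; results derived from it are labelled "simplified model" in
reports.

Units: geometry in mm, segment length in m; conductivities follow the
conventions Lp [m s-1 MPa-1], k_wall [m2 s-1 MPa-1], mu [MPa s];
Kx [m4 s-1 MPa-1], Kr [m3 s-1 MPa-1], kr [m s-1 MPa-1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError

MM = 1e-3  # mm -> m

# Defaults for the subcellular hydraulic parameters; literature-plausible
# magnitudes for young maize roots (cell membrane conductivity ~5e-7
# m s-1 MPa-1, wall conductivity such that the apoplastic path is of the
# same order as the membrane path for ~20 um walls).
DEFAULT_LP = 5.3e-7
DEFAULT_K_WALL = 2.4e-11
DEFAULT_MU = 1.0e-9          # water at 20 C, MPa s
DEFAULT_SEGMENT_LENGTH = 0.01  # m


@dataclass
class AnatomyParams:
    """Anatomical inputs on the standard trait scales (areas mm^2, mm, counts)."""

    rxsa: float                 # root cross-section area, mm^2
    tsa_rxsa: float             # stele:root area ratio
    ccfn: int                   # cortical cell file number
    ccs: float                  # cortical cell size, mm^2
    aa: float = 0.0             # aerenchyma area, mm^2
    nmv: int = 0                # metaxylem vessel count
    md: float = 0.0             # metaxylem vessel diameter, mm
    tca: float | None = None    # total cortical area, mm^2 (optional check)
    xa: float | None = None     # percent cortex as aerenchyma (optional check)
    ma: float | None = None     # individual vessel area, mm^2 (optional check)
    mva: float | None = None    # total vessel area, mm^2 (optional check)

    @property
    def tsa(self) -> float:
        """Total stele area, derived from the ratio and the section area."""
        return self.tsa_rxsa * self.rxsa

    def __post_init__(self):
        for name in ("rxsa", "ccs"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        for name in ("aa", "md"):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be non-negative")
        if not (0 < self.tsa_rxsa < 1):
            raise GeometryError("stele:root ratio must be in (0, 1)")
        if int(self.ccfn) < 1:
            raise GeometryError("cortical cell file number must be >= 1")
        if int(self.nmv) < 0:
            raise GeometryError("metaxylem vessel count must be >= 0")
        if self.xa is not None and not (0 <= self.xa <= 100):
            raise GeometryError("percent cortex as aerenchyma must be in [0, 100]")
        if self.nmv and self.ma and self.mva:
            if abs(self.mva - self.nmv * self.ma) > 0.1 * max(self.mva, 1e-12):
                raise GeometryError("MVA inconsistent with NMV x MA (>10%)")

    @classmethod
    def from_traits(cls, row: dict | pd.Series) -> "AnatomyParams":
        """Build from a record keyed by the standard trait codes."""
        get = row.get if isinstance(row, dict) else (lambda k: row.get(k, None))
        return cls(
            rxsa=float(row["RXSA"]), tsa_rxsa=float(row["TSA.RXSA"]),
            ccfn=int(round(float(row["CCFN"]))), ccs=float(row["CCS"]),
            aa=float(row["AA"]) if "AA" in row else 0.0,
            nmv=int(round(float(row["NMV"]))) if "NMV" in row else 0,
            md=float(row["MD"]) if "MD" in row else 0.0,
            tca=float(row["TCA"]) if "TCA" in row else None,
            xa=float(row["X.A"]) if "X.A" in row else None,
            ma=float(row["MA"]) if "MA" in row else None,
            mva=float(row["MVA"]) if "MVA" in row else None,
        )


@dataclass
class Layer:
    name: str
    kind: str            # epidermis | cortex | endodermis | pericycle | stele
    r_outer: float       # mm
    r_inner: float       # mm
    cell_count: int
    aerenchyma_frac: float = 0.0

    @property
    def thickness(self) -> float:
        return self.r_outer - self.r_inner

    @property
    def r_mid(self) -> float:
        return 0.5 * (self.r_outer + self.r_inner)

    @property
    def area(self) -> float:
        return np.pi * (self.r_outer ** 2 - self.r_inner ** 2)


@dataclass
class CrossSection:
    """Concentric-layer geometry of one root segment (outermost first)."""

    layers: list[Layer]
    vessel_diameters: list[float]        # mm
    vessel_circle_radius: float          # mm
    segment_length: float = DEFAULT_SEGMENT_LENGTH  # m
    params: AnatomyParams | None = None

    def __post_init__(self):
        r = [lay.r_outer for lay in self.layers]
        if any(b >= a for a, b in zip(r, r[1:])):
            raise GeometryError("layer radii must decrease inward")
        for lay in self.layers:
            if lay.thickness <= 0:
                raise GeometryError(f"layer {lay.name} has non-positive thickness")

    @property
    def outer_radius(self) -> float:
        return self.layers[0].r_outer

    @property
    def stele_radius(self) -> float:
        for lay in self.layers:
            if lay.kind == "endodermis":
                return lay.r_inner
        return self.layers[-1].r_outer

    def recomputed_areas(self) -> dict:
        """Areas implied by the geometry, for round-trip checks."""
        tca = sum(l.area for l in self.layers if l.kind == "cortex")
        aa = sum(l.aerenchyma_frac * l.area for l in self.layers if l.kind == "cortex")
        tsa = np.pi * self.stele_radius ** 2
        return {"TSA": tsa, "TCA": tca, "AA": aa,
                "RXSA": np.pi * self.outer_radius ** 2}

    def layer_table(self) -> pd.DataFrame:
        rows = [{
            "layer": l.name, "kind": l.kind, "r_outer_mm": l.r_outer,
            "r_inner_mm": l.r_inner, "thickness_mm": l.thickness,
            "cell_count": l.cell_count, "aerenchyma_frac": l.aerenchyma_frac,
        } for l in self.layers]
        return pd.DataFrame(rows)

    def to_svg(self, path) -> None:
        """Minimal rendering: concentric annuli, lacunae sectors, vessels."""
        R = self.outer_radius
        s = 200.0 / R
        cx = cy = 210.0
        parts = ['<svg xmlns="http://www.w3.org/2000/svg" width="420" height="420">']
        fill = {"epidermis": "#8d6e63", "cortex": "#aed581", "endodermis": "#7cb342",
                "pericycle": "#fff176", "stele": "#ffb74d"}
        for lay in self.layers:
            parts.append(
                f'<circle cx="{cx}" cy="{cy}" r="{lay.r_outer * s:.2f}" '
                f'fill="{fill[lay.kind]}" stroke="#555" stroke-width="0.5"/>')
            if lay.aerenchyma_frac > 0:
                n_lac = 8
                for k in range(n_lac):
                    a0 = 2 * np.pi * (k + 0.5 * (1 - lay.aerenchyma_frac)) / n_lac
                    a1 = a0 + 2 * np.pi * lay.aerenchyma_frac / n_lac
                    rm = lay.r_mid * s
                    x0, y0 = cx + rm * np.cos(a0), cy + rm * np.sin(a0)
                    x1, y1 = cx + rm * np.cos(a1), cy + rm * np.sin(a1)
                    parts.append(
                        f'<path d="M {x0:.1f} {y0:.1f} A {rm:.1f} {rm:.1f} 0 0 1 '
                        f'{x1:.1f} {y1:.1f}" stroke="white" fill="none" '
                        f'stroke-width="{max(lay.thickness * s * 0.8, 1):.1f}"/>')
        for k, d in enumerate(self.vessel_diameters):
            a = 2 * np.pi * k / max(len(self.vessel_diameters), 1)
            vx = cx + self.vessel_circle_radius * s * np.cos(a)
            vy = cy + self.vessel_circle_radius * s * np.sin(a)
            parts.append(f'<circle cx="{vx:.1f}" cy="{vy:.1f}" r="{d / 2 * s:.2f}" '
                         'fill="#e3f2fd" stroke="#1565c0" stroke-width="0.8"/>')
        parts.append("</svg>")
        with open(path, "w") as fh:
            fh.write("\n".join(parts))


@dataclass
class HydraulicParams:
    """Subcellular hydraulic scenario (Casparian strip on by default)."""

    lp: float = DEFAULT_LP           # m s-1 MPa-1
    k_wall: float = DEFAULT_K_WALL   # m2 s-1 MPa-1
    mu: float = DEFAULT_MU           # MPa s
    casparian: bool = True

    def __post_init__(self):
        if self.lp <= 0 or self.k_wall < 0 or self.mu <= 0:
            raise ConfigError("hydraulic parameters must be positive")


@dataclass
class HydraulicProperties:
    kr: float    # m s-1 MPa-1 (per root surface area)
    Kr: float    # m3 s-1 MPa-1 (per segment)
    Kx: float    # m4 s-1 MPa-1


MIN_CELL_THICKNESS = 0.004   # mm; cortical ring thinner than this cannot hold cells
MAX_RING_AERENCHYMA = 0.95   # circumferential fraction cap per ring


def build_cross_section(params: AnatomyParams,
                        t_epidermis: float = 0.02,
                        t_endodermis: float = 0.02,
                        segment_length: float = DEFAULT_SEGMENT_LENGTH) -> CrossSection:
    """Reconstruct a concentric-layer cross-section from anatomical traits.

    Outer radius from RXSA, stele radius from the derived TSA, fixed
    epidermis/endodermis thickness, the remaining annulus split into CCFN
    equal cortical rings.  Aerenchyma is assigned as a circumferential
    fraction from the mid-cortex outward until the lacunae area reaches AA.
    NMV vessels of diameter MD sit uniformly on a circle at 0.6 x stele
    radius.
    """
    r_out = float(np.sqrt(params.rxsa / np.pi))
    r_stele = float(np.sqrt(params.tsa / np.pi))
    cortex_outer = r_out - t_epidermis
    cortex_inner = r_stele + t_endodermis
    cortex_thickness = cortex_outer - cortex_inner
    ccfn = int(params.ccfn)
    if cortex_thickness < ccfn * MIN_CELL_THICKNESS:
        raise GeometryError(
            f"cortex {cortex_thickness:.4f} mm cannot hold {ccfn} cell files "
            f"(needs >= {ccfn * MIN_CELL_THICKNESS:.4f} mm)")

    layers = [Layer("epidermis", "epidermis", r_out, cortex_outer, cell_count=max(
        int(2 * np.pi * (r_out - t_epidermis / 2) / t_epidermis), 4))]
    dr = cortex_thickness / ccfn
    cell_d = 2.0 * np.sqrt(params.ccs / np.pi)
    rings = []
    for i in range(ccfn):
        ro = cortex_outer - i * dr
        ri = ro - dr
        n_cells = max(int(2 * np.pi * 0.5 * (ro + ri) / cell_d), 4)
        rings.append(Layer(f"cortex_{i + 1}", "cortex", ro, ri, n_cells))
    # aerenchyma: fill mid-cortex rings outward until the lacunae area is AA
    remaining = params.aa
    order = list(range(ccfn // 2, -1, -1)) + list(range(ccfn // 2 + 1, ccfn))
    # mid ring first, then outward (toward the epidermis), then inner rings
    order = sorted(range(ccfn), key=lambda i: (abs(i - ccfn // 2), i))
    max_total = sum(MAX_RING_AERENCHYMA * r.area for r in rings)
    if params.aa > max_total:
        raise GeometryError(
            f"aerenchyma area {params.aa:.3f} mm^2 exceeds the attainable "
            f"{max_total:.3f} mm^2 for this cortex")
    for i in order:
        if remaining <= 0:
            break
        take = min(remaining, MAX_RING_AERENCHYMA * rings[i].area)
        rings[i].aerenchyma_frac = take / rings[i].area
        remaining -= take
    layers.extend(rings)

    layers.append(Layer("endodermis", "endodermis", cortex_inner, r_stele,
                        cell_count=max(int(2 * np.pi * r_stele / t_endodermis), 4)))
    t_peri = min(0.015, 0.25 * r_stele)
    layers.append(Layer("pericycle", "pericycle", r_stele, r_stele - t_peri,
                        cell_count=max(int(2 * np.pi * r_stele / 0.02), 4)))
    v_circle = 0.6 * r_stele
    stele_inner = v_circle
    if stele_inner >= r_stele - t_peri:
        stele_inner = 0.9 * (r_stele - t_peri)
    layers.append(Layer("stele_ground", "stele", r_stele - t_peri, stele_inner,
                        cell_count=max(int((r_stele - t_peri) ** 2 / params.ccs), 4)))

    nmv, md = int(params.nmv), float(params.md)
    if nmv > 0:
        if md <= 0:
            raise GeometryError("vessels requested with non-positive diameter")
        if v_circle + md / 2 >= r_stele - t_peri:
            raise GeometryError(
                f"vessel diameter {md:.4f} mm does not fit inside the stele "
                f"(circle radius {v_circle:.4f}, stele radius {r_stele:.4f})")
        if nmv > 1:
            spacing = 2.0 * v_circle * np.sin(np.pi / nmv)
            if spacing < md:
                raise GeometryError(
                    f"{nmv} vessels of diameter {md:.4f} mm overlap on the "
                    f"placement circle (centre spacing {spacing:.4f} mm)")
    vessels = [md] * nmv
    return CrossSection(layers=layers, vessel_diameters=vessels,
                        vessel_circle_radius=v_circle,
                        segment_length=segment_length, params=params)


# ---------------------------------------------------------------------------
# Conductances
# ---------------------------------------------------------------------------

def axial_conductance(section: CrossSection, hyd: HydraulicParams) -> float:
    """Hagen-Poiseuille sum over metaxylem vessels (protoxylem ignored)."""
    d_m = np.asarray(section.vessel_diameters, dtype=float) * MM
    return float(np.sum(np.pi * d_m ** 4) / (128.0 * hyd.mu))


def _layer_conductances(section: CrossSection, hyd: HydraulicParams
                        ) -> list[tuple[float, float]]:
    """Per layer (outermost first): (membrane-path, apoplast-path)
    conductances in m3 s-1 MPa-1."""
    L = section.segment_length
    out = []
    for lay in section.layers:
        r = lay.r_mid * MM
        t = lay.thickness * MM
        circ = 2.0 * np.pi * r * L
        g_mem = circ * hyd.lp / 2.0          # two membranes in series
        g_apo = circ * hyd.k_wall / t
        if hyd.casparian and lay.kind == "endodermis":
            g_apo = 0.0
        scale = 1.0 - lay.aerenchyma_frac
        out.append((g_mem * scale, g_apo * scale))
    return out


def radial_properties(section: CrossSection, hyd: HydraulicParams) -> HydraulicProperties:
    """Series composition of per-layer parallel membrane/apoplast paths."""
    inv = 0.0
    for name, (g_mem, g_apo) in zip((l.name for l in section.layers),
                                    _layer_conductances(section, hyd)):
        g = g_mem + g_apo
        if g <= 0:
            raise GeometryError(f"layer {name} has zero total conductance")
        inv += 1.0 / g
    Kr = 1.0 / inv
    surface = 2.0 * np.pi * section.outer_radius * MM * section.segment_length
    kr = Kr / surface
    return HydraulicProperties(kr=kr, Kr=Kr, Kx=axial_conductance(section, hyd))


def radial_conductance_network(section: CrossSection, hyd: HydraulicParams) -> float:
    """Independent Kirchhoff solve of the same shell network.

    Builds explicit pressure nodes for each layer boundary plus an interior
    node per membrane path (two membrane edges in series), assembles the
    full conductance (Laplacian) matrix, applies unit pressure across the
    section, and reads the flux.  Serves as the oracle for
    :func:`radial_properties`.
    """
    pairs = _layer_conductances(section, hyd)
    n_layers = len(pairs)
    # boundary nodes 0..n_layers (0 = outside, n_layers = innermost);
    # one midpoint node per layer for the two-membrane series path
    n_nodes = (n_layers + 1) + n_layers
    edges = []
    for i, (g_mem, g_apo) in enumerate(pairs):
        a, b = i, i + 1
        mid = n_layers + 1 + i
        if g_mem > 0:
            edges.append((a, mid, 2.0 * g_mem))   # each half is one membrane
            edges.append((mid, b, 2.0 * g_mem))
        if g_apo > 0:
            edges.append((a, b, g_apo))
    G = np.zeros((n_nodes, n_nodes))
    for a, b, g in edges:
        G[a, a] += g
        G[b, b] += g
        G[a, b] -= g
        G[b, a] -= g
    # Dirichlet: P=1 at node 0 (outside), P=0 at innermost boundary
    fixed = {0: 1.0, n_layers: 0.0}
    free = [i for i in range(n_nodes) if i not in fixed]
    rhs = np.zeros(len(free))
    for k, i in enumerate(free):
        for j, pv in fixed.items():
            rhs[k] -= G[i, j] * pv
    P = np.zeros(n_nodes)
    for j, pv in fixed.items():
        P[j] = pv
    if free:
        sub = G[np.ix_(free, free)]
        try:
            P[free] = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError as exc:
            raise GeometryError("degenerate shell network") from exc
    # flux out of the fixed outside node
    flux = sum(g * (P[a] - P[b]) for a, b, g in edges if a == 0)
    flux += sum(g * (P[b] - P[a]) for a, b, g in edges if b == 0)
    return float(flux)


# ---------------------------------------------------------------------------
# Cluster composites
# ---------------------------------------------------------------------------

def cluster_composite(projections: pd.DataFrame, labels: pd.Series,
                      training_means: dict, hyd: HydraulicParams | None = None,
                      segment_length: float = DEFAULT_SEGMENT_LENGTH,
                      render_dir=None) -> pd.DataFrame:
    """Median trait values per cluster -> composite anatomy -> hydraulics.

    Traits not in the projection (RXSA in particular) are filled with the
    training-panel mean.  Returns one row per cluster with the composite
    parameters, recomputed areas and kr/Kr/Kx; clusters with fewer than
    3 members are flagged.
    """
    hyd = hyd or HydraulicParams()
    shared = projections.index.intersection(labels.index)
    if len(shared) < len(labels):
        missing = len(labels) - len(shared)
        raise ConfigError(f"{missing} labelled accessions lack projections")
    rows = []
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        med = projections.loc[members].median()
        rec = dict(med)
        for trait, value in training_means.items():
            if trait not in rec or pd.isna(rec.get(trait)):
                rec[trait] = value
        # composites are built from the primary parameters; derived traits
        # (MA, MVA, X.A, TCA) are recomputed from geometry, since medians
        # of products differ from products of medians
        params = AnatomyParams(
            rxsa=float(rec["RXSA"]), tsa_rxsa=float(rec["TSA.RXSA"]),
            ccfn=int(round(float(rec["CCFN"]))), ccs=float(rec["CCS"]),
            aa=float(rec.get("AA", 0.0)), nmv=int(round(float(rec.get("NMV", 0)))),
            md=float(rec.get("MD", 0.0)))
        section = build_cross_section(params, segment_length=segment_length)
        props = radial_properties(section, hyd)
        areas = section.recomputed_areas()
        if render_dir is not None:
            from pathlib import Path
            out = Path(render_dir)
            out.mkdir(parents=True, exist_ok=True)
            section.to_svg(out / f"cluster_{cl}.svg")
            section.layer_table().to_csv(out / f"cluster_{cl}_layers.csv",
                                         index=False)
        rows.append({
            "cluster": cl, "n_members": int(len(members)),
            "small_cluster": bool(len(members) < 3),
            **{f"median_{k}": float(v) for k, v in med.items()},
            "RXSA_used": params.rxsa, "TSA_used": params.tsa,
            "TCA_geom": areas["TCA"], "AA_geom": areas["AA"],
            "kr": props.kr, "Kr": props.Kr, "Kx": props.Kx,
        })
    return pd.DataFrame(rows)


def random_valid_params(rng: np.random.Generator) -> AnatomyParams:
    """Random anatomically consistent parameter draw (testing utility)."""
    rxsa = rng.uniform(0.5, 2.5)
    tsa_rxsa = rng.uniform(0.1, 0.3)
    tsa = tsa_rxsa * rxsa
    r_out = np.sqrt(rxsa / np.pi)
    r_s = np.sqrt(tsa / np.pi)
    cortex = (r_out - 0.02) - (r_s + 0.02)
    ccfn = int(rng.integers(6, min(16, max(7, int(cortex / MIN_CELL_THICKNESS)))))
    ccs = rng.uniform(2e-4, 8e-4)
    tca = np.pi * ((r_out - 0.02) ** 2 - (r_s + 0.02) ** 2)
    aa = rng.uniform(0.0, 0.4) * tca
    md = rng.uniform(0.03, min(0.10, 0.35 * r_s))
    v_circle = 0.6 * r_s
    nmv_max = int(np.pi / np.arcsin(min(md / (2 * v_circle), 0.999)))
    nmv = int(rng.integers(1, max(2, min(20, nmv_max))))
    return AnatomyParams(rxsa=rxsa, tsa_rxsa=tsa_rxsa, ccfn=ccfn, ccs=ccs,
                        aa=aa, nmv=nmv, md=md, tca=tca)
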