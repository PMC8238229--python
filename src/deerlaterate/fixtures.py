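"""Synthetic fixtures: ideal-helix backbone, planted rotamers, noisy traces.

Generates complete inputs for every other module with no external data:
an ideal alpha-helix backbone written as a valid PDB, clash-filtered
pseudo-rotamer clouds with a planted ground-truth rotamer per labeled
site, and DEER traces synthesized through the full forward chain
(distribution -> broadening -> form factor -> background composition)
with i.i.d. Gaussian noise on the real channel and a pure-noise
imaginary channel of the same amplitude, mirroring how the imaginary
component serves as a noise proxy in real measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .forward import (
    BackgroundModel,
    DistanceGrid,
    broaden,
    compose_trace,
    default_grid,
    distance_distribution,
    form_factor,
)
from .multilateration import CoordinateModel, TraceNetwork, _pair_sigma
from .rotamers import (
    BackboneResidue,
    PseudoRotamerCloud,
    clash_filter,
    generate_cloud,
    reconstruct_cb,
    write_ensemble,
)
from .trace_io import DeerTrace, ResidueId, estimate_noise, format_residue_id, write_trace

__all__ = [
    "FixtureSpec",
    "SyntheticNetwork",
    "make_backbone",
    "make_network",
    "recovery_fixture_spec",
]

_HELIX_RISE = 1.5      # A per residue
_HELIX_TWIST = 100.0   # degrees per residue
_HELIX_RADIUS = 2.3    # A, CA radius of an ideal alpha-helix


@dataclass
class FixtureSpec:
    """Complete description of one synthetic dataset."""

    n_residues: int = 40
    label_sites: list[int] = field(default_factory=list)
    #: (site_u, site_v, trace length in us, time step in ns)
    pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    #: per-site [(candidate index, weight), ...]; None -> drawn at build time
    planted_rotamers: dict[int, list[tuple[int, float]]] | None = None
    noise_sigma: float = 0.01
    #: per-trace (mod_depth, k, d); None -> drawn deterministically from seed
    backgrounds: list[tuple[float, float, float]] | None = None
    b_factor_profile: float | list[float] = 26.32
    n_candidates: int = 50
    clash_cutoff: float = 2.5
    chain: str = "A"
    seed: int = 0
    #: planted pair distances are re-drawn until they land in this window
    planted_distance_window: tuple[float, float] = (18.0, 70.0)

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        sites = set(self.label_sites)
        for u, v, t_max, dt in self.pairs:
            if u not in sites or v not in sites:
                raise ValueError(f"pair ({u}, {v}) references a non-labeled site")
            if u == v:
                raise ValueError(f"pair ({u}, {v}) repeats a site")
            if t_max <= 0 or dt <= 0:
                raise ValueError("trace length and step must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def site_id(self, site: int) -> ResidueId:
        return (self.chain, site)


def _helix_ca(i: np.ndarray) -> np.ndarray:
    theta = np.deg2rad(_HELIX_TWIST) * i
    return np.column_stack(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
    )


def make_backbone(
    spec: FixtureSpec,
    path: str | Path | None = None,
) -> list[BackboneResidue]:
    """Ideal alpha-helix backbone (rise 1.5 A, 100 deg/residue) with B-factors.

    N and C are placed along the chain direction at standard bond
    lengths and CB by ideal tetrahedral geometry, which is sufficient
    for clash filtering and cloud generation. Written as a valid PDB
    when ``path`` is given.
    """
    ca = _helix_ca(np.arange(spec.n_residues, dtype=float))
    # helix continues past both termini, so terminal residues keep ideal geometry
    ext = _helix_ca(np.arange(-1, spec.n_residues + 1, dtype=float))
    prev = ext[:-2]
    nxt = ext[2:]
    bfac = np.broadcast_to(
        np.asarray(spec.b_factor_profile, dtype=float), (spec.n_residues,)
    )
    residues: list[BackboneResidue] = []
    for i in range(spec.n_residues):
        to_prev = prev[i] - ca[i]
        to_next = nxt[i] - ca[i]
        n_at = ca[i] + 1.46 * to_prev / np.linalg.norm(to_prev)
        c_at = ca[i] + 1.52 * to_next / np.linalg.norm(to_next)
        radial = c_at - np.array([0.0, 0.0, c_at[2]])
        o_at = c_at + 1.23 * radial / np.linalg.norm(radial)
        cb_at = reconstruct_cb(n_at, ca[i], c_at)
        residues.append(
            BackboneResidue(
                chain=spec.chain,
                seqnum=i + 1,
                n=n_at,
                ca=ca[i],
                c=c_at,
                o=o_at,
                cb=cb_at,
                b_ca=float(bfac[i]),
            )
        )
    if path is not None:
        _write_pdb(residues, path)
    return residues


def _write_pdb(residues: list[BackboneResidue], path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = "synthetic-helix"
    model = gemmi.Model("1")
    chain = gemmi.Chain(residues[0].chain)
    for res in residues:
        r = gemmi.Residue()
        r.name = "ALA"
        r.seqid = gemmi.SeqId(res.seqnum, " ")
        for name, coords, element in (
            ("N", res.n, "N"),
            ("CA", res.ca, "C"),
            ("C", res.c, "C"),
            ("O", res.o, "O"),
            ("CB", res.cb, "C"),
        ):
            if coords is None:
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*coords)
            atom.b_iso = res.b_ca
            atom.occ = 1.0
            r.add_atom(atom)
        chain.add_residue(r)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class SyntheticNetwork:
    """A built fixture: candidate clouds, planted truth, and noisy traces."""

    spec: FixtureSpec
    residues: list[BackboneResidue]
    clouds: dict[ResidueId, PseudoRotamerCloud]
    planted: CoordinateModel
    traces: list[DeerTrace]

    def to_trace_network(
        self,
        d_policy: str = "fixed",
        grid: DistanceGrid | None = None,
        estimate: bool = True,
    ) -> TraceNetwork:
        """Package for fitting; optionally estimate noise from the imaginary channel."""
        if estimate:
            for tr in self.traces:
                estimate_noise(tr)
        return TraceNetwork(
            traces=self.traces,
            clouds=self.clouds,
            grid=grid or default_grid(),
            d_policy=d_policy,
        )

    def planted_positions(self) -> dict[ResidueId, np.ndarray]:
        return {rid: cloud.centroid() for rid, cloud in self.planted.clouds.items()}


def _survivor_map(
    full: PseudoRotamerCloud, filtered: PseudoRotamerCloud
) -> dict[int, int]:
    """original candidate index -> surviving local index (exact positions)."""
    out: dict[int, int] = {}
    j = 0
    for i in range(full.n_positions):
        if j < filtered.n_positions and np.array_equal(full.positions[i], filtered.positions[j]):
            out[i] = j
            j += 1
    return out


def _draw_planted(
    spec: FixtureSpec,
    clouds: dict[ResidueId, PseudoRotamerCloud],
    surv_maps: dict[ResidueId, dict[int, int]],
    rng: np.random.Generator,
) -> dict[int, list[tuple[int, float]]]:
    """One surviving rotamer per site, re-drawn until every planted pair
    distance falls inside the spec's window."""
    lo, hi = spec.planted_distance_window
    sites = list(spec.label_sites)
    for _attempt in range(5000):
        choice = {
            s: int(rng.choice(sorted(surv_maps[spec.site_id(s)].keys()))) for s in sites
        }
        ok = True
        for u, v, _tm, _dt in spec.pairs:
            pu = clouds[spec.site_id(u)].positions[surv_maps[spec.site_id(u)][choice[u]]]
            pv = clouds[spec.site_id(v)].positions[surv_maps[spec.site_id(v)][choice[v]]]
            d = float(np.linalg.norm(pu - pv))
            if not (lo <= d <= hi):
                ok = False
                break
        if ok:
            return {s: [(choice[s], 1.0)] for s in sites}
    raise ValueError("could not place planted rotamers inside the distance window")


def make_network(
    spec: FixtureSpec,
    out_dir: str | Path | None = None,
    grid: DistanceGrid | None = None,
) -> SyntheticNetwork:
    """Build the complete synthetic dataset a fitting run consumes.

    Traces are synthesized from the planted model through the full
    forward chain and, when ``out_dir`` is given, written to disk in the
    ASCII trace dialect together with the PDB, a pair manifest, and the
    ground-truth ensemble coordinates.
    """
    grid = grid or default_grid()
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    residues = make_backbone(spec, path=(out / "structure.pdb") if out else None)
    by_seq = {r.seqnum: r for r in residues}

    clouds: dict[ResidueId, PseudoRotamerCloud] = {}
    surv_maps: dict[ResidueId, dict[int, int]] = {}
    for site in spec.label_sites:
        full = generate_cloud(by_seq[site], n_candidates=spec.n_candidates)
        filt = clash_filter(full, residues, cutoff=spec.clash_cutoff)
        rid = spec.site_id(site)
        clouds[rid] = filt
        surv_maps[rid] = _survivor_map(full, filt)

    planted_spec = spec.planted_rotamers
    if planted_spec is None:
        planted_spec = _draw_planted(spec, clouds, surv_maps, rng)
    planted_clouds: dict[ResidueId, PseudoRotamerCloud] = {}
    for site in spec.label_sites:
        rid = spec.site_id(site)
        weights = np.zeros(clouds[rid].n_positions)
        for orig_idx, wgt in planted_spec[site]:
            if orig_idx not in surv_maps[rid]:
                raise ValueError(
                    f"site {site}: planted rotamer {orig_idx} was removed by the clash filter"
                )
            if wgt <= 0:
                raise ValueError(f"site {site}: planted weight must be positive")
            weights[surv_maps[rid][orig_idx]] = wgt
        planted_clouds[rid] = clouds[rid].with_weights(weights)

    backgrounds = spec.backgrounds
    if backgrounds is None:
        backgrounds = [
            (float(rng.uniform(0.25, 0.40)), float(rng.uniform(0.1, 0.3)), 3.0)
            for _ in spec.pairs
        ]
    if len(backgrounds) != len(spec.pairs):
        raise ValueError("one background parameter triple is required per pair")

    traces: list[DeerTrace] = []
    bg_models: dict[str, BackgroundModel] = {}
    for (u, v, t_max_us, dt_ns), (lam, k, d) in zip(spec.pairs, backgrounds):
        rid_u, rid_v = spec.site_id(u), spec.site_id(v)
        n_pts = int(round(t_max_us * 1000.0 / dt_ns)) + 1
        time_us = np.arange(n_pts) * dt_ns / 1000.0
        dist = distance_distribution(planted_clouds[rid_u], planted_clouds[rid_v], grid)
        dist = broaden(dist, _pair_sigma(planted_clouds[rid_u], planted_clouds[rid_v]))
        trace_id = f"{format_residue_id(rid_u)}-{format_residue_id(rid_v)}"
        v_intra = form_factor(dist, time_us, pair_id=trace_id)
        bg = BackgroundModel(mod_depth=lam, k=k, d=d)
        v_sim = compose_trace(v_intra, bg, time_us)
        real = v_sim + rng.normal(0.0, spec.noise_sigma, n_pts)
        imag = rng.normal(0.0, spec.noise_sigma, n_pts)
        traces.append(
            DeerTrace(
                trace_id=trace_id,
                residue_u=rid_u,
                residue_v=rid_v,
                time_us=time_us,
                real=real,
                imag=imag,
            )
        )
        bg_models[trace_id] = bg

    planted = CoordinateModel(clouds=planted_clouds, backgrounds=bg_models)

    if out is not None:
        manifest = []
        for tr in traces:
            fname = f"trace_{tr.trace_id.replace(':', '')}.dat"
            write_trace(tr, out / fname)
            manifest.append(
                {
                    "trace_path": fname,
                    "trace_id": tr.trace_id,
                    "residue_u": format_residue_id(tr.residue_u),
                    "residue_v": format_residue_id(tr.residue_v),
                    "truncate_ns": 0,
                }
            )
        (out / "manifest.yaml").write_text(yaml.safe_dump({"pairs": manifest}))
        write_ensemble(planted_clouds, out / "ground_truth.txt")
    return SyntheticNetwork(
        spec=spec, residues=residues, clouds=clouds, planted=planted, traces=traces
    )


def recovery_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The canonical recovery benchmark: 6 sites, 10 interconnected pairs.

    Every site is restrained by at least three pairs, mirroring the
    interconnectivity that makes multilateration well-posed. Traces are
    2.0 us at 16 ns steps with noise s.d. 0.01. Clouds carry 12
    candidates per site (roughly 4-5 A apart), so the planted rotamer is
    the only constellation consistent with the decays: pairwise
    distances determine positions only up to rigid motion, and a dense
    candidate set would leave that degeneracy unresolved no matter how
    well the decays are fit.
    """
    sites = [5, 12, 19, 26, 33, 40]
    pairs = [
        (5, 19), (5, 26), (5, 33), (5, 40),
        (12, 26), (12, 33), (12, 40),
        (19, 33), (19, 40),
        (26, 40),
    ]
    return FixtureSpec(
        n_residues=40,
        label_sites=sites,
        pairs=[(u, v, 2.0, 16.0) for u, v in pairs],
        noise_sigma=0.01,
        n_candidates=12,
        seed=seed,
    )
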