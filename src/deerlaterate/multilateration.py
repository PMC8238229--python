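"""Simulated-annealing multilateration of pseudo-rotamer weights.

Given an interconnected network of DEER traces and per-residue candidate
clouds, each replica reweights all clouds by Metropolis moves on single
rotamer weights, scored by the noise-normalized log-likelihood

    lnL = -(n_total/2) ln( (1/n_total) sum_i sum_t ((V_exp - V_sim)/sigma_i)^2 )

against the fully composed simulated decays. Rounds of
``trials_per_trace x n_traces`` trials run at a Boltzmann temperature
that decays asymptotically to zero and resets to ``kT_init`` between
rounds; a round without any accepted improvement shrinks the move
magnitude tenfold, and the replica stops once the magnitude reaches
1e-4. Replicas are ranked by AICc, which counts every nonzero-weight
rotamer plus the per-trace background parameters, so parsimonious
ensembles win ties in fit quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .forward import (
    BackgroundModel,
    DistanceDistribution,
    DistanceGrid,
    R_MIN_ANGSTROM,
    broaden,
    broadening_matrix,
    compose_trace,
    default_grid,
    dipolar_kernel,
    distance_distribution,
    form_factor,
)
from .rotamers import PseudoRotamerCloud, pair_rmsf, rmsf_from_bfactor
from .trace_io import DeerTrace, ResidueId, format_residue_id

__all__ = [
    "AnnealConfig",
    "CoordinateModel",
    "TraceNetwork",
    "log_likelihood",
    "aicc",
    "propose_move",
    "undo_move",
    "metropolis_accept",
    "run_replica",
    "run_replicas",
    "confidence_bands",
    "predict_heldout",
    "model_pair_distribution",
]

SSR_MEAN_FLOOR = 1e-12


@dataclass
class AnnealConfig:
    """Annealing schedule parameters (defaults follow the published protocol)."""

    kT_init: float = 1.5
    trials_per_trace: int = 2500
    abort_after_failures: int = 500
    move_magnitude_init: float = 0.1
    magnitude_shrink_factor: float = 10.0
    magnitude_floor: float = 1e-4
    #: fraction of kT_init reached by the last scheduled trial of a round
    kT_decay: float = 0.01
    seed: int = 0
    max_rounds: int = 300

    def __post_init__(self) -> None:
        for name in (
            "kT_init", "trials_per_trace", "abort_after_failures",
            "move_magnitude_init", "magnitude_shrink_factor",
            "magnitude_floor", "kT_decay",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.magnitude_floor >= self.move_magnitude_init:
            raise ValueError("magnitude_floor must be < move_magnitude_init")


@dataclass
class CoordinateModel:
    """One replica's complete solution: refined clouds + per-trace backgrounds."""

    clouds: dict[ResidueId, PseudoRotamerCloud]
    backgrounds: dict[str, BackgroundModel]
    log_likelihood: float | None = None
    aicc: float | None = None
    k_params: int | None = None
    seed: int | None = None
    n_rounds: int | None = None
    ssr_initial: float | None = None
    ssr_final: float | None = None
    #: best noise-normalized SSR at the end of each annealing round
    round_ssr: list[float] | None = None

    @property
    def n_nonzero(self) -> int:
        return int(sum(int(np.count_nonzero(c.weights > 0)) for c in self.clouds.values()))


@dataclass
class TraceNetwork:
    """Traces, candidate clouds, and fit configuration for one dataset."""

    traces: list[DeerTrace]
    clouds: dict[ResidueId, PseudoRotamerCloud]
    grid: DistanceGrid = field(default_factory=default_grid)
    d_policy: str = "fixed"  # "fixed": d = 3.0; "free": released after round 1
    r_min: float = R_MIN_ANGSTROM

    def __post_init__(self) -> None:
        if self.d_policy not in ("fixed", "free"):
            raise ValueError("d_policy must be 'fixed' or 'free'")
        ids = set()
        for tr in self.traces:
            if tr.trace_id in ids:
                raise ValueError(f"duplicate trace_id {tr.trace_id}")
            ids.add(tr.trace_id)
            for rid in (tr.residue_u, tr.residue_v):
                if rid not in self.clouds:
                    raise ValueError(
                        f"trace {tr.trace_id}: residue {format_residue_id(rid)} has no cloud"
                    )
        self._cache: dict | None = None

    @property
    def residue_order(self) -> list[ResidueId]:
        return sorted(self.clouds.keys())

    @property
    def n_total(self) -> int:
        return int(sum(tr.n_points for tr in self.traces))

    def bg_params_per_trace(self) -> int:
        return 2 if self.d_policy == "fixed" else 3


def _pair_sigma(cloud_u: PseudoRotamerCloud, cloud_v: PseudoRotamerCloud) -> float:
    return pair_rmsf(
        rmsf_from_bfactor(cloud_u.residue.b_ca),
        rmsf_from_bfactor(cloud_v.residue.b_ca),
    )


def _build_inputs(network: TraceNetwork) -> dict:
    """Flatten the network into the padded arrays the jit engine consumes."""
    if network._cache is not None:
        return network._cache
    order = network.residue_order
    res_index = {rid: i for i, rid in enumerate(order)}
    sizes = [network.clouds[rid].n_positions for rid in order]
    res_off = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
    rot_res = np.concatenate(
        [np.full(n, i, dtype=np.int64) for i, n in enumerate(sizes)]
    )
    grid = network.grid
    centers = grid.centers
    nb = centers.size
    n_traces = len(network.traces)
    max_nt = max(tr.n_points for tr in network.traces)
    max_n = max(sizes)

    u_res = np.zeros(n_traces, dtype=np.int64)
    v_res = np.zeros(n_traces, dtype=np.int64)
    nt_arr = np.zeros(n_traces, dtype=np.int64)
    tmat = np.zeros((n_traces, max_nt))
    vexp = np.zeros((n_traces, max_nt))
    sigma2 = np.zeros(n_traces)
    a3 = np.zeros((n_traces, max_nt, nb))
    svec = np.zeros((n_traces, nb))
    didx = np.zeros((n_traces, max_n, max_n), dtype=np.int64)

    keep_mask = (centers >= network.r_min).astype(float)
    for ti, tr in enumerate(network.traces):
        if tr.noise_sigma is None:
            raise ValueError(f"trace {tr.trace_id}: noise_sigma is not set")
        cu = network.clouds[tr.residue_u]
        cv = network.clouds[tr.residue_v]
        u_res[ti] = res_index[tr.residue_u]
        v_res[ti] = res_index[tr.residue_v]
        nt = tr.n_points
        nt_arr[ti] = nt
        tmat[ti, :nt] = tr.time_us
        vexp[ti, :nt] = tr.real
        sigma2[ti] = tr.noise_sigma**2
        g = broadening_matrix(centers, _pair_sigma(cu, cv))
        mg = keep_mask[:, None] * g
        kmat = dipolar_kernel(centers[None, :] / 10.0, tr.time_us[:, None])
        a3[ti, :nt, :] = kmat @ mg
        svec[ti] = mg.sum(axis=0)
        diff = cu.positions[:, None, :] - cv.positions[None, :, :]
        dists = np.sqrt(np.sum(diff * diff, axis=-1))
        didx[ti, : cu.n_positions, : cv.n_positions] = grid.bin_index(dists)

    # residue -> trace incidence (CSR)
    lists: list[list[int]] = [[] for _ in order]
    for ti, tr in enumerate(network.traces):
        lists[res_index[tr.residue_u]].append(ti)
        lists[res_index[tr.residue_v]].append(ti)
    res_tr_off = np.zeros(len(order) + 1, dtype=np.int64)
    for i, lst in enumerate(lists):
        res_tr_off[i + 1] = res_tr_off[i] + len(lst)
    res_tr = np.array([ti for lst in lists for ti in lst] or [0], dtype=np.int64)

    network._cache = dict(
        order=order,
        res_off=res_off,
        rot_res=rot_res,
        u_res=u_res,
        v_res=v_res,
        nt_arr=nt_arr,
        tmat=tmat,
        vexp=vexp,
        sigma2=sigma2,
        a3=a3,
        svec=svec,
        didx=didx,
        res_tr_off=res_tr_off,
        res_tr=res_tr,
        lam_grid=np.linspace(0.05, 0.6, 12),
        k_grid=np.concatenate([[1e-6], np.geomspace(1e-3, 3.0, 16)]),
        d_grid_free=np.array([2.0, 2.5, 3.0, 3.5]),
    )
    return network._cache


# ---------------------------------------------------------------------------
# likelihood / model selection


def log_likelihood(
    model: CoordinateModel,
    traces: list[DeerTrace],
    grid: DistanceGrid | None = None,
    r_min: float = R_MIN_ANGSTROM,
) -> float:
    """Noise-normalized log-likelihood of a coordinate model (time domain)."""
    grid = grid or default_grid()
    n_total = 0
    ssr = 0.0
    for tr in traces:
        if tr.noise_sigma is None:
            raise ValueError(f"trace {tr.trace_id}: noise_sigma is not set")
        for rid in (tr.residue_u, tr.residue_v):
            if rid not in model.clouds:
                raise ValueError(f"residue {format_residue_id(rid)} has no refined cloud")
        cu = model.clouds[tr.residue_u]
        cv = model.clouds[tr.residue_v]
        dist = broaden(distance_distribution(cu, cv, grid), _pair_sigma(cu, cv))
        v_intra = form_factor(dist, tr.time_us, r_min=r_min, pair_id=tr.trace_id)
        v_sim = compose_trace(v_intra, model.backgrounds[tr.trace_id], tr.time_us)
        ssr += float(np.sum(((tr.real - v_sim) / tr.noise_sigma) ** 2))
        n_total += tr.n_points
    mean = max(ssr / n_total, SSR_MEAN_FLOOR)
    return -0.5 * n_total * math.log(mean)


def aicc(log_likelihood: float, k_params: int, n_total: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n_total <= k_params + 1:
        raise ValueError(f"n_total ({n_total}) must exceed k_params + 1 ({k_params + 1})")
    return (
        -2.0 * log_likelihood
        + 2.0 * k_params
        + 2.0 * k_params * (k_params + 1) / (n_total - k_params - 1)
    )


# ---------------------------------------------------------------------------
# move set (reference implementation mirrored by the jit engine)


def propose_move(
    model: CoordinateModel,
    magnitude: float,
    rng: np.random.Generator,
) -> tuple[CoordinateModel, tuple[ResidueId, int, float]]:
    """Perturb one rotamer weight in place; return (model, undo record).

    A rotamer is chosen uniformly across all residues; its weight is
    incremented by a uniform draw from [-magnitude, magnitude] and
    clipped at zero. A move that would zero out an entire residue is
    redrawn.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    order = sorted(model.clouds.keys())
    sizes = np.array([model.clouds[rid].n_positions for rid in order])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = int(offsets[-1])
    while True:
        g = int(rng.integers(total))
        r = int(np.searchsorted(offsets, g, side="right") - 1)
        rid = order[r]
        local = g - int(offsets[r])
        weights = model.clouds[rid].weights
        delta = float(rng.uniform(-magnitude, magnitude))
        new_w = max(weights[local] + delta, 0.0)
        if new_w == 0.0 and weights.sum() - weights[local] <= 0.0:
            continue  # would leave the residue with all-zero weights: redraw
        undo = (rid, local, float(weights[local]))
        weights[local] = new_w
        return model, undo


def undo_move(model: CoordinateModel, undo: tuple[ResidueId, int, float]) -> None:
    rid, local, old = undo
    model.clouds[rid].weights[local] = old


def metropolis_accept(
    lnl_new: float,
    lnl_old: float,
    kT: float,
    rng: np.random.Generator,
) -> bool:
    """Boltzmann rule on the energy -lnL: improvements always accepted."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    if lnl_new >= lnl_old:
        return True
    return bool(rng.random() < math.exp((lnl_new - lnl_old) / kT))


# ---------------------------------------------------------------------------
# replica driver


def run_replica(network: TraceNetwork, config: AnnealConfig | None = None) -> CoordinateModel:
    """Run one annealing replica; returns the refined coordinate model."""
    config = config or AnnealConfig()
    inp = _build_inputs(network)
    w, lam, kk, dd, ssr_tot, ssr_init, n_rounds, _trials, round_ssr = _engine.run_anneal(
        config.seed,
        inp["res_off"], inp["rot_res"],
        inp["u_res"], inp["v_res"], inp["nt_arr"],
        inp["tmat"], inp["vexp"], inp["sigma2"],
        inp["a3"], inp["svec"], inp["didx"],
        inp["res_tr_off"], inp["res_tr"],
        inp["lam_grid"], inp["k_grid"], inp["d_grid_free"],
        config.kT_init, config.kT_decay,
        config.trials_per_trace, config.abort_after_failures,
        config.move_magnitude_init, config.magnitude_floor,
        config.magnitude_shrink_factor,
        0 if network.d_policy == "fixed" else 1,
        config.max_rounds,
        SSR_MEAN_FLOOR,
    )
    order = inp["order"]
    res_off = inp["res_off"]
    clouds = {
        rid: network.clouds[rid].with_weights(w[res_off[i]:res_off[i + 1]])
        for i, rid in enumerate(order)
    }
    backgrounds = {
        tr.trace_id: BackgroundModel(mod_depth=float(lam[ti]), k=float(kk[ti]), d=float(dd[ti]))
        for ti, tr in enumerate(network.traces)
    }
    n_total = network.n_total
    lnl = -0.5 * n_total * math.log(max(ssr_tot / n_total, SSR_MEAN_FLOOR))
    model = CoordinateModel(
        clouds=clouds,
        backgrounds=backgrounds,
        log_likelihood=lnl,
        seed=config.seed,
        n_rounds=int(n_rounds),
        ssr_initial=float(ssr_init),
        ssr_final=float(ssr_tot),
        round_ssr=[float(x) for x in round_ssr],
    )
    model.k_params = model.n_nonzero + len(network.traces) * network.bg_params_per_trace()
    model.aicc = aicc(lnl, model.k_params, n_total)
    return model


def run_replicas(
    network: TraceNetwork,
    n_replicas: int,
    base_seed: int = 0,
    config: AnnealConfig | None = None,
) -> list[CoordinateModel]:
    """Independent replicas with seeds base_seed + i, ranked by AICc ascending."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    config = config or AnnealConfig()
    models = []
    for i in range(n_replicas):
        cfg = AnnealConfig(**{**config.__dict__, "seed": base_seed + i})
        models.append(run_replica(network, cfg))
    return sorted(models, key=lambda m: m.aicc)  # stable: ties keep replica order


# ---------------------------------------------------------------------------
# outputs


def model_pair_distribution(
    model: CoordinateModel,
    pair: tuple[ResidueId, ResidueId],
    grid: DistanceGrid | None = None,
) -> DistanceDistribution:
    """Broadened distance distribution between two refined clouds."""
    grid = grid or default_grid()
    for rid in pair:
        if rid not in model.clouds:
            raise ValueError(f"residue {format_residue_id(rid)} has no refined cloud")
    cu, cv = model.clouds[pair[0]], model.clouds[pair[1]]
    return broaden(distance_distribution(cu, cv, grid), _pair_sigma(cu, cv))


def predict_heldout(
    model: CoordinateModel,
    pair: tuple[ResidueId, ResidueId],
    grid: DistanceGrid | None = None,
) -> DistanceDistribution:
    """Predict the distribution of a pair that was not in the training network."""
    return model_pair_distribution(model, pair, grid)


def confidence_bands(
    models: list[CoordinateModel],
    pair: tuple[ResidueId, ResidueId],
    n_top: int = 5,
    grid: DistanceGrid | None = None,
) -> DistanceDistribution:
    """Central distribution and 95% bands from the n_top lowest-AICc models.

    The central value is the per-bin mean over the models' broadened
    distributions; the bands are the per-bin 2.5th/97.5th percentiles.
    ``models`` is assumed ranked by AICc (as returned by run_replicas).
    """
    if n_top > len(models):
        raise ValueError(f"n_top ({n_top}) exceeds number of models ({len(models)})")
    grid = grid or default_grid()
    dists = np.array(
        [model_pair_distribution(m, pair, grid).probabilities for m in models[:n_top]]
    )
    central = dists.mean(axis=0)
    lo = np.percentile(dists, 2.5, axis=0)
    hi = np.percentile(dists, 97.5, axis=0)
    return DistanceDistribution(
        bin_centers=grid.centers,
        probabilities=central / central.sum(),
        band_lo=lo,
        band_hi=hi,
    )
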