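"""Config-driven in silico experiments.

Implemented experiments: wild type (growing tissue with an intact organizer
stripe), replicated edge ablation with recoil fitting, a fast-cycling clone
pressing on the organizer, an ectopic "eight"-shaped organizer that rounds
up, five lack-of-function mutants (no organizer, uniform affinity, no cable,
random cleavage, uniform cycle duration), and a parameter-robustness scan.
Every run is reproducible from its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cycle import CycleParams, new_clock
from .dynamics import EventLog, SimState, TopologyThresholds, evolve, relax
from .identity import CellIdentity, dv_boundary_edges, fence_breach_edges
from .mechanics import ForceEngine, MechanicsParams, ablate_edge, classify_edge
from .mesh import InitialConditionSpec, TissueMesh, build_hex_patch
from . import metrics as mt

__all__ = [
    "ExperimentConfig",
    "make_state",
    "run_wild_type",
    "run_ablation_experiment",
    "run_clone",
    "run_ectopic_eight",
    "run_mutant",
    "robustness_scan",
    "MUTANT_VARIANTS",
    "MUTANT_PANEL_WINDOWS",
    "mutant_panel_config",
    "mutant_overrides",
]

MUTANT_VARIANTS = (
    "no_organizer",
    "uniform_affinity",
    "no_cable",
    "random_cleavage",
    "uniform_cycle",
)

# evaluation window per variant, in mean bulk cycles, and whether the run may
# stop at the first fence breach.  Fast phenotypes (mixing without an
# organizer, stripe widening) show within the three-cycle wild-type window;
# the slow disruptions (loss of differential affinity, random cleavage) are
# first-passage events evaluated on a late snapshot, and the cable knockout
# is read at 3.5 cycles where the stripe has thinned but not yet torn.
MUTANT_PANEL_WINDOWS = {
    "no_organizer": (3.0, False),
    "uniform_affinity": (4.5, True),
    "no_cable": (3.5, False),
    "random_cleavage": (4.5, True),
    "uniform_cycle": (3.0, False),
}


def mutant_panel_config(
    variant: str,
    initial_condition: Optional[InitialConditionSpec] = None,
    seed: int = 0,
) -> ExperimentConfig:
    """Canonical configuration of one mutant-panel run."""
    cycles, stop = MUTANT_PANEL_WINDOWS[variant]
    return ExperimentConfig(
        experiment="mutant",
        mutant_variant=variant,
        initial_condition=initial_condition or InitialConditionSpec(nrows=12, ncols=12),
        run_cycles=cycles,
        stop_on_breach=stop,
        seed=seed,
    )


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one run.

    ``run_cycles`` is the run length in units of the mean bulk cycle
    duration; the wild-type default of three cycles lets the population grow
    roughly eightfold.  ``sample_every`` (time units) sets the cadence at
    which fence integrity and width are sampled.
    """

    experiment: str = "wild_type"
    mutant_variant: Optional[str] = None
    initial_condition: InitialConditionSpec = field(default_factory=InitialConditionSpec)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    thresholds: TopologyThresholds = field(default_factory=TopologyThresholds)
    run_cycles: float = 3.0
    seed: int = 0
    sample_every: float = 10.0
    identity_mode: str = "maintenance"
    stop_on_breach: bool = False  # end a run at the first fence breach

    def __post_init__(self) -> None:
        if self.experiment == "mutant" and self.mutant_variant not in MUTANT_VARIANTS:
            raise ValueError(
                f"mutant experiment requires a variant in {MUTANT_VARIANTS}"
            )
        if self.experiment != "mutant" and self.mutant_variant is not None:
            raise ValueError("mutant_variant is only valid for the mutant experiment")
        if self.identity_mode not in ("maintenance", "inherit"):
            raise ValueError("identity_mode must be 'maintenance' or 'inherit'")

    @property
    def t_end(self) -> float:
        return self.run_cycles * self.cycle.mean_cycle("C")


def make_state(config: ExperimentConfig) -> SimState:
    """Build the initial simulation state (mesh, identities, random clocks)."""
    config.mechanics.validate()
    rng = np.random.default_rng(config.seed)
    ic = replace(config.initial_condition, seed=config.seed)
    mesh, identities = build_hex_patch(ic)
    clocks = {
        cid: new_clock(config.cycle, identities[cid].cell_type, 0.0, rng, random_phase=True)
        for cid in mesh.cells
    }
    return SimState(
        mesh=mesh,
        identities=identities,
        clocks=clocks,
        mechanics=config.mechanics,
        cycle=config.cycle,
        thresholds=config.thresholds,
        rng=rng,
        events=EventLog(),
        identity_mode=config.identity_mode,
    )


@dataclass
class RunResult:
    """Outcome of a growth run plus its integrity time series."""

    config: ExperimentConfig
    state: SimState
    samples: pd.DataFrame  # time, n_cells, breaches, width_median
    initial_cells: int

    @property
    def fence_intact(self) -> bool:
        return bool((self.samples["breaches"] == 0).all())

    @property
    def final_cells(self) -> int:
        return self.state.mesh.n_cells()

    def metrics_report(self) -> dict:
        state = self.state
        report: dict = {
            "n_cells": state.mesh.n_cells(),
            "fold_increase": state.mesh.n_cells() / self.initial_cells,
            "fence_intact": self.fence_intact,
        }
        sides = mt.side_histogram(state.mesh)
        report["side_histogram"] = {int(k): float(v) for k, v in sides.items()}
        report["modal_sides"] = int(sides.idxmax())
        areas = mt.area_by_sides(state.mesh)
        report["area_by_sides"] = {int(k): float(v) for k, v in areas.items()}
        widths = mt.organizer_width(state.mesh, state.identities)
        report["width_median"] = float(widths["width"].median())
        report["width_min"] = int(widths["width"].min())
        mix = mt.mixing_index(state.mesh, state.identities)
        report["heterotypic_contacts"] = mix.heterotypic_contacts
        report["interface_roughness"] = mix.roughness
        try:
            bstats = mt.boundary_angle_stats(state.mesh, state.identities)
            report["boundary_angle_dispersion"] = bstats.dispersion
            report["boundary_angle_length_corr"] = bstats.correlation
        except ValueError:
            report["boundary_angle_dispersion"] = math.nan
            report["boundary_angle_length_corr"] = math.nan
        return report


class _FenceBreached(Exception):
    pass


def _run_growth(config: ExperimentConfig, state: SimState) -> RunResult:
    samples: List[dict] = []

    def sample(s: SimState) -> None:
        widths = mt.organizer_width(s.mesh, s.identities)
        breaches = len(fence_breach_edges(s.mesh, s.identities))
        samples.append(
            {
                "time": s.mesh.time,
                "n_cells": s.mesh.n_cells(),
                "breaches": breaches,
                "width_median": float(widths["width"].median()),
                "width_min": int(widths["width"].min()),
            }
        )
        if config.stop_on_breach and breaches > 0:
            raise _FenceBreached

    n0 = state.mesh.n_cells()
    try:
        sample(state)
        evolve(state, config.t_end, hook=sample, hook_every=config.sample_every)
        sample(state)
    except _FenceBreached:
        pass
    return RunResult(
        config=config,
        state=state,
        samples=pd.DataFrame(samples),
        initial_cells=n0,
    )


def run_wild_type(config: Optional[ExperimentConfig] = None) -> RunResult:
    """Grow the wild-type tissue for ``run_cycles`` mean bulk cycles."""
    config = config or ExperimentConfig()
    return _run_growth(config, make_state(config))


# -- ablation ----------------------------------------------------------------


@dataclass
class AblationResult:
    edge_class: str
    fits: List[mt.RelaxationFit]
    dropped: int

    @property
    def tau_mean(self) -> float:
        return float(np.mean([f.tau for f in self.fits]))

    @property
    def tau_std(self) -> float:
        return float(np.std([f.tau for f in self.fits]))

    @property
    def v0_mean(self) -> float:
        return float(np.mean([f.v0 for f in self.fits]))

    @property
    def v0_std(self) -> float:
        return float(np.std([f.v0 for f in self.fits]))


def _candidate_edges(state: SimState, edge_class: str) -> List[Tuple[int, int]]:
    """Interior edges of the requested class away from the tissue border."""
    mesh = state.mesh
    exterior_cells = {
        cells[0] for e, cells in mesh.edge_map().items() if len(cells) == 1
    }
    out = []
    for e, cells in mesh.edge_map().items():
        if len(cells) != 2 or any(c in exterior_cells for c in cells):
            continue
        if classify_edge(mesh, state.identities, e) == edge_class:
            out.append(e)
    return out


def ablation_trace(
    state: SimState,
    edge: Tuple[int, int],
    duration: float,
    record_every: int = 1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Ablate one edge and record the separation of its two vertices.

    The cycle clocks are frozen during the recording so that the trace
    reflects pure mechanical relaxation.  Returns (t since ablation, d(t)).
    """
    state.ablated, (v1, v2) = ablate_edge(state.mesh, state.ablated, edge)
    t0 = state.mesh.time
    ts: List[float] = []
    ds: List[float] = []

    counter = {"k": 0}

    def tracer(s: SimState, engine: ForceEngine) -> None:
        if counter["k"] % record_every == 0:
            ts.append(s.mesh.time - t0)
            ds.append(float(np.linalg.norm(s.mesh.positions[v2] - s.mesh.positions[v1])))
        counter["k"] += 1

    ts.append(0.0)
    ds.append(float(np.linalg.norm(state.mesh.positions[v2] - state.mesh.positions[v1])))
    evolve(state, t0 + duration, freeze_cycle=True, trace=tracer)
    return np.asarray(ts), np.asarray(ds)


def run_ablation_experiment(
    config: Optional[ExperimentConfig] = None,
    edge_classes: Sequence[str] = ("C-C", "boundary"),
    n_replicates: int = 20,
    duration: Optional[float] = None,
    fit_window: Optional[float] = None,
    relax_tol: float = 1e-4,
) -> Dict[str, AblationResult]:
    """Replicated in silico laser ablations per edge class.

    The tissue is prepared at mechanical equilibrium: the preferred areas
    are set to the reference area (a latent tissue) and the network is
    relaxed with frozen clocks until the maximum vertex force drops below
    ``relax_tol``.  Each replicate then ablates one randomly chosen interior
    edge of the requested class and fits the exponential recoil
    d(t) = d_inf - (d_inf-d0) e^(-t/tau) to the rising phase of the trace
    (up to the separation maximum, capped at ``fit_window``): the primary
    recoil is single-exponential, while the slow drift that follows it
    reflects tissue-scale rearrangement and is excluded.  Reports mean and
    standard deviation of tau and of the initial recoil velocity v0 per
    class; failed fits are dropped and counted.
    """
    config = config or ExperimentConfig()
    mu = config.mechanics.mu
    base = make_state(config)
    for ck in base.clocks.values():
        ck.preferred_area = config.cycle.a_ref
    relax(base, force_tol=relax_tol, max_time=500.0 * mu)
    duration = duration if duration is not None else 12.0 * mu
    fit_window = fit_window if fit_window is not None else 8.0 * mu

    results: Dict[str, AblationResult] = {}
    for cls in edge_classes:
        rng = np.random.default_rng(config.seed + 1)
        candidates = _candidate_edges(base, cls)
        if not candidates:
            raise ValueError(f"no interior edges of class {cls} in the tissue")
        fits: List[mt.RelaxationFit] = []
        dropped = 0
        for rep in range(n_replicates):
            edge = candidates[rng.integers(len(candidates))]
            trial = SimState(
                mesh=base.mesh.copy(),
                identities=dict(base.identities),
                clocks={c: replace(ck) for c, ck in base.clocks.items()},
                mechanics=base.mechanics,
                cycle=base.cycle,
                thresholds=base.thresholds,
                rng=np.random.default_rng(config.seed + 100 + rep),
                events=EventLog(),
                identity_mode=base.identity_mode,
            )
            ts, ds = ablation_trace(trial, edge, duration)
            keep = min(int(np.argmax(ds)) + 1, int(np.searchsorted(ts, fit_window) + 1))
            try:
                fits.append(mt.fit_relaxation(ts[:keep], ds[:keep]))
            except (RuntimeError, ValueError):
                dropped += 1
        results[cls] = AblationResult(edge_class=cls, fits=fits, dropped=dropped)
    return results


# -- clone and ectopic organizer --------------------------------------------


@dataclass
class CloneResult:
    run: RunResult
    near_deflection: float  # boundary |y - y0| near the clone
    far_deflection: float  # same, far from the clone

    @property
    def fence_intact(self) -> bool:
        return self.run.fence_intact

    def clone_in_one_compartment(self) -> bool:
        comps = {
            i.compartment
            for c, i in self.run.state.identities.items()
            if i.clone and c in self.run.state.mesh.cells
        }
        return len(comps) <= 1


def run_clone(config: Optional[ExperimentConfig] = None) -> CloneResult:
    """Fast-cycling clone abutting the organizer: pressure bends the fence.

    The clone keeps bulk mechanics but cycles at half the bulk duration.
    Reports the local deflection of the DV boundary (median |y - y_mid|)
    within the clone's x extent versus outside it.
    """
    if config is None:
        ic = InitialConditionSpec()
        config = ExperimentConfig(
            experiment="clone", initial_condition=ic, run_cycles=2.5
        )
    ic = config.initial_condition
    if ic.clone is None:
        stripe_low = (ic.nrows // 2) - 1
        config = replace(
            config,
            initial_condition=replace(
                ic, clone=(stripe_low - 3, ic.ncols // 2, 1.5)
            ),
        )
    state = make_state(config)
    if not any(i.clone for i in state.identities.values()):
        raise ValueError("clone region is empty")
    run = _run_growth(config, state)

    mesh, idents = run.state.mesh, run.state.identities
    clone_cells = [c for c, i in idents.items() if i.clone and c in mesh.cells]
    xs = np.concatenate([mesh.cell_vertices(c)[:, 0] for c in clone_cells])
    clone_span = (xs.min(), xs.max())
    edges = dv_boundary_edges(mesh, idents)
    if not edges:
        return CloneResult(run=run, near_deflection=math.nan, far_deflection=math.nan)
    pos = mesh.positions
    mids = np.array([0.5 * (pos[a] + pos[b]) for a, b in edges])
    near = (mids[:, 0] >= clone_span[0]) & (mids[:, 0] <= clone_span[1])
    if not near.any() or near.all():
        return CloneResult(run=run, near_deflection=math.nan, far_deflection=math.nan)
    # baseline: the undisturbed boundary height, estimated far from the clone
    y0 = float(np.median(mids[~near, 1]))
    dev = np.abs(mids[:, 1] - y0)
    near_d = float(np.median(dev[near]))
    far_d = float(np.median(dev[~near]))
    return CloneResult(run=run, near_deflection=near_d, far_deflection=far_d)


def organizer_isoperimetric_ratio(mesh: TissueMesh, identities) -> float:
    """P^2 / (4 pi A) of the union of organizer cells (1 for a disc)."""
    from shapely.ops import unary_union
    from shapely.geometry import Polygon

    polys = [
        Polygon(mesh.cell_vertices(c))
        for c, i in identities.items()
        if i.character == "O" and c in mesh.cells
    ]
    if not polys:
        raise ValueError("no organizer cells")
    union = unary_union(polys)
    return float(union.length**2 / (4.0 * math.pi * union.area))


@dataclass
class EctopicResult:
    run: RunResult
    times: np.ndarray
    isoperimetric: np.ndarray  # P^2/(4 pi A) of the organizer region

    def ratio_decreased(self) -> bool:
        q = max(1, len(self.isoperimetric) // 4)
        return float(np.mean(self.isoperimetric[-q:])) < float(
            np.mean(self.isoperimetric[:q])
        )


def run_ectopic_eight(config: Optional[ExperimentConfig] = None) -> EctopicResult:
    """Ectopic eight-shaped organizer rounding up by interfacial tension.

    The patch sits inside one compartment; its rim edges carry the cable
    (Notch activity, not compartment identity, defines the cable), so the
    region minimizes its interface like a fluid droplet and the
    isoperimetric ratio decays toward 1.
    """
    if config is None:
        nrows = ncols = 14
        r0, c0 = nrows // 2 + 1, ncols // 2
        ic = InitialConditionSpec(
            nrows=nrows,
            ncols=ncols,
            stripe_rows=(),
            ectopic=((r0, c0 - 2), (r0, c0 + 1), 1.6),
        )
        config = ExperimentConfig(
            experiment="ectopic_eight",
            initial_condition=ic,
            mechanics=MechanicsParams(ectopic_rim_cable=True),
            run_cycles=1.0,
        )
    state = make_state(config)
    times: List[float] = []
    ratios: List[float] = []

    def sample(s: SimState) -> None:
        times.append(s.mesh.time)
        ratios.append(organizer_isoperimetric_ratio(s.mesh, s.identities))

    n0 = state.mesh.n_cells()
    sample(state)
    evolve(state, config.t_end, hook=sample, hook_every=config.sample_every)
    sample(state)
    run = RunResult(
        config=config,
        state=state,
        samples=pd.DataFrame(
            {"time": times, "n_cells": np.nan, "breaches": 0, "width_median": np.nan}
        ),
        initial_cells=n0,
    )
    return EctopicResult(run=run, times=np.asarray(times), isoperimetric=np.asarray(ratios))


# -- mutants -----------------------------------------------------------------


def mutant_overrides(
    variant: str, mech: MechanicsParams, cyc: CycleParams
) -> Tuple[MechanicsParams, CycleParams, Optional[Tuple[int, ...]]]:
    """Parameter/initial-condition overrides defining each mutant.

    no_organizer: all cells bulk (stripe removed).
    uniform_affinity: one line tension for C-C, O-O and O-C; the cable
      (boundary line tension and edge contractility) is retained.
    no_cable: boundary edges revert to plain O-O tension, no edge
      contractility.
    random_cleavage: divisions at uniformly random orientations.
    uniform_cycle: organizer cycle duration equal to the bulk's.
    """
    stripe_rows: Optional[Tuple[int, ...]] = None
    if variant == "no_organizer":
        stripe_rows = ()
    elif variant == "uniform_affinity":
        mech = mech.copy(lambda_oo=mech.lambda_cc, lambda_oc=mech.lambda_cc)
    elif variant == "no_cable":
        mech = mech.copy(lambda_boundary=mech.lambda_oo, gamma_edge=0.0)
    elif variant == "random_cleavage":
        cyc = cyc.copy(random_cleavage=True)
    elif variant == "uniform_cycle":
        cyc = cyc.copy(t_det_organizer=cyc.t_det_bulk)
    else:
        raise ValueError(f"unknown mutant variant: {variant}")
    return mech, cyc, stripe_rows


@dataclass
class MutantResult:
    variant: str
    run: RunResult
    verdict: dict  # fence_intact, width_min, width_median, boundary dispersion


def run_mutant(config: ExperimentConfig) -> MutantResult:
    """Run one lack-of-function mutant and quantify the outcome."""
    variant = config.mutant_variant
    assert variant is not None
    mech, cyc, stripe_rows = mutant_overrides(variant, config.mechanics, config.cycle)
    ic = config.initial_condition
    if stripe_rows is not None:
        ic = replace(ic, stripe_rows=stripe_rows)
    config = replace(config, initial_condition=ic, mechanics=mech, cycle=cyc)
    run = _run_growth(config, make_state(config))
    state = run.state
    widths = mt.organizer_width(state.mesh, state.identities)
    try:
        dispersion = mt.boundary_angle_stats(state.mesh, state.identities).dispersion
    except ValueError:
        dispersion = math.nan
    verdict = {
        "fence_intact": run.fence_intact,
        "width_min": int(run.samples["width_min"].min()),
        "width_median": float(widths["width"].median()),
        "boundary_angle_dispersion": float(dispersion),
        "final_breaches": len(fence_breach_edges(state.mesh, state.identities)),
    }
    return MutantResult(variant=variant, run=run, verdict=verdict)


# -- robustness scan ---------------------------------------------------------

# parameters perturbed by the scan; the exterior line tension and the (null)
# cable coefficient of non-boundary edges are excluded
SCAN_MECHANICS = (
    "k_elastic",
    "gamma",
    "lambda_cc",
    "lambda_oo",
    "lambda_oc",
    "lambda_boundary",
    "gamma_edge",
)
SCAN_CYCLE = (
    "t_det_bulk",
    "t_det_organizer",
    "dispersion_fraction",
    "a_div",
    "sigma_theta",
)


@dataclass
class RobustnessResult:
    trials: pd.DataFrame  # distance, functional, one column per parameter factor
    delta_max: float

    def fraction_functional(self, bins: int = 2) -> pd.DataFrame:
        df = self.trials
        edges = np.linspace(0.0, df["distance"].max() + 1e-12, bins + 1)
        rows = []
        for k in range(bins):
            sel = (df["distance"] >= edges[k]) & (df["distance"] < edges[k + 1])
            if k == bins - 1:
                sel |= df["distance"] == edges[k + 1]
            n = int(sel.sum())
            rows.append(
                {
                    "bin_low": edges[k],
                    "bin_high": edges[k + 1],
                    "n": n,
                    "fraction": float(df.loc[sel, "functional"].mean()) if n else math.nan,
                }
            )
        return pd.DataFrame(rows)


def robustness_scan(
    config: Optional[ExperimentConfig] = None,
    n_trials: int = 100,
    delta_max: float = 0.5,
    exterior_only: bool = False,
) -> RobustnessResult:
    """Random parameter perturbations: does the organizer still hold?

    Each trial multiplies every perturbable parameter by (1 + u) with
    u ~ Uniform(-delta_max, delta_max) independently, records the Euclidean
    distance |u| to the wild type, runs the configured window, and flags the
    trial functional when no C(D)-C(V) contact appears at any sampled time.
    ``exterior_only`` instead varies just the exterior line tension.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(config.seed + 7)
    rows: List[dict] = []
    names = ("lambda_exterior",) if exterior_only else SCAN_MECHANICS + SCAN_CYCLE
    for trial in range(n_trials):
        u = rng.uniform(-delta_max, delta_max, size=len(names)) if delta_max > 0 else np.zeros(len(names))
        mech = config.mechanics
        cyc = config.cycle
        for name, uk in zip(names, u):
            if name in SCAN_MECHANICS or name == "lambda_exterior":
                mech = mech.copy(**{name: getattr(mech, name) * (1.0 + uk)})
            elif name == "a_div":
                # perturb the excess over a_ref so the threshold stays valid
                cyc = cyc.copy(a_div=cyc.a_ref + (cyc.a_div - cyc.a_ref) * (1.0 + uk))
            else:
                cyc = cyc.copy(**{name: getattr(cyc, name) * (1.0 + uk)})
        trial_cfg = replace(config, mechanics=mech, cycle=cyc, seed=config.seed + 1000 + trial)
        run = _run_growth(trial_cfg, make_state(trial_cfg))
        row = {
            "trial": trial,
            "distance": float(np.linalg.norm(u)),
            "functional": run.fence_intact,
        }
        row.update({f"u_{n}": float(v) for n, v in zip(names, u)})
        rows.append(row)
    return RobustnessResult(trials=pd.DataFrame(rows), delta_max=delta_max)
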