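"""Simulation designs: treatment x landscape x dispersal sweeps.

A design enumerates cells — (landscape kind, landscape replicate,
dispersal, treatment, fixed virulence where applicable) — and runs each
cell with its own deterministically derived seed, so any single cell can
be re-run in isolation and reproduce its sweep result bit-for-bit.
Presets mirror the two standard study designs: the focal evolutionary /
shuffled / fixed-virulence comparison across a dispersal gradient, and
the degree-stratified ecological-consequence sweep at d = 0.1, 0.5, 1.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as vstats
from .core import InitSpec, ModelParams, run
from .landscapes import (
    LandscapeGraph,
    OcnAnnealConfig,
    generate_circular,
    generate_ocn,
    generate_rgg,
    generate_spiky,
    read_landscape,
)

__all__ = [
    "ExperimentDesign",
    "run_design",
    "preset_fig1",
    "preset_fig3",
    "derive_seed",
    "cell_seed",
]

log = logging.getLogger("virunet")

#: default dispersal grid for dispersal-gradient sweeps
DEFAULT_D_GRID = (0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0)
#: fixed-virulence grid v = 0.8, 0.82, ..., 1.0
DEFAULT_FIXED_V_GRID = tuple(
    float(v) for v in np.round(np.arange(0.80, 1.0001, 0.02), 2)
)

_KIND_CODE = {"rgg": 1, "ocn": 2, "circular": 3, "spiky": 4, "custom": 5}
_TREAT_CODE = {"evolving": 1, "fixed": 2, "shuffled": 3}


def derive_seed(*parts: int) -> int:
    """Deterministically fold integer key parts into a 31-bit seed."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentDesign:
    """A full factorial sweep over landscape kinds, replicates, dispersal
    values and treatments.

    ``treatments`` may contain ``evolving`` (virulence evolves),
    ``shuffled`` (evolving plus post-transmission kin-structure breaking),
    and ``fixed`` (ecological control; crossed with ``fixed_v_grid``).
    """

    landscape_kinds: tuple[str, ...] = ("rgg", "ocn")
    n_landscapes: int = 10
    dispersal_grid: tuple[float, ...] = DEFAULT_D_GRID
    treatments: tuple[str, ...] = ("evolving",)
    fixed_v_grid: tuple[float, ...] = DEFAULT_FIXED_V_GRID
    T: int = 2500
    record_window: int = 100
    master_seed: int = 0
    base_params: dict = field(default_factory=dict)
    init: InitSpec = field(default_factory=InitSpec)
    # landscape generator settings
    rgg_n: int = 100
    rgg_r: float = 0.15
    ocn_config: OcnAnnealConfig = field(default_factory=OcnAnnealConfig)
    circular_n: int = 100
    circular_k: int = 1
    spiky_hubs: int = 10
    spiky_leaves: int = 9
    custom_landscape: str | None = None  # edge-list path for kind="custom"
    scale: str = "desk"  # label carried into outputs

    def validate(self) -> None:
        if not self.landscape_kinds:
            raise ValueError("landscape_kinds must be non-empty")
        for k in self.landscape_kinds:
            if k not in _KIND_CODE:
                raise ValueError(f"unknown landscape kind {k!r}")
        for t in self.treatments:
            if t not in _TREAT_CODE:
                raise ValueError(f"unknown treatment {t!r}")
        if not self.dispersal_grid:
            raise ValueError("dispersal_grid must be non-empty")
        if "fixed" in self.treatments and not self.fixed_v_grid:
            raise ValueError("fixed treatment requires a fixed_v_grid")
        if self.T < self.record_window:
            raise ValueError("T must be >= record_window")
        if self.n_landscapes < 1:
            raise ValueError("n_landscapes must be >= 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ocn_config"] = dataclasses.asdict(self.ocn_config)
        d["init"] = dataclasses.asdict(self.init)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        if "ocn_config" in d and isinstance(d["ocn_config"], dict):
            d["ocn_config"] = OcnAnnealConfig(**d["ocn_config"])
        if "init" in d and isinstance(d["init"], dict):
            d["init"] = InitSpec(**d["init"])
        for key in ("landscape_kinds", "dispersal_grid", "treatments", "fixed_v_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def landscape_seed(design: ExperimentDesign, kind: str, rep: int) -> int:
    return derive_seed(design.master_seed, 7, _KIND_CODE[kind], rep)


def cell_seed(
    design: ExperimentDesign,
    kind: str,
    rep: int,
    d: float,
    treatment: str,
    fixed_v: float | None,
) -> int:
    """Per-cell simulation seed; unique per design cell, stable across
    partial re-runs and execution order."""
    return derive_seed(
        design.master_seed,
        11,
        _KIND_CODE[kind],
        rep,
        int(round(d * 10_000)),
        _TREAT_CODE[treatment],
        0 if fixed_v is None else int(round(fixed_v * 10_000)),
    )


def make_landscape(design: ExperimentDesign, kind: str, rep: int) -> LandscapeGraph:
    """Generate (or load) landscape replicate ``rep`` of a given kind."""
    seed = landscape_seed(design, kind, rep)
    if kind == "rgg":
        return generate_rgg(design.rgg_n, design.rgg_r, seed=seed)
    if kind == "ocn":
        return generate_ocn(design.ocn_config, seed=seed)
    if kind == "circular":
        return generate_circular(design.circular_n, design.circular_k)
    if kind == "spiky":
        return generate_spiky(design.spiky_hubs, design.spiky_leaves)
    if kind == "custom":
        if design.custom_landscape is None:
            raise ValueError("custom kind requires custom_landscape path")
        return read_landscape(design.custom_landscape)
    raise ValueError(f"unknown landscape kind {kind!r}")


def _cell_params(
    design: ExperimentDesign, d: float, treatment: str, fixed_v: float | None
) -> ModelParams:
    params = ModelParams(**design.base_params)
    params.d = float(d)
    params.T = design.T
    params.shuffle = treatment == "shuffled"
    if treatment == "fixed":
        params.virulence_mode = "fixed"
        params.fixed_v = float(fixed_v)
    else:
        params.virulence_mode = "evolving"
    return params


def _iter_cells(design: ExperimentDesign):
    for kind in design.landscape_kinds:
        for rep in range(design.n_landscapes):
            for d in design.dispersal_grid:
                for treatment in design.treatments:
                    v_grid = (
                        design.fixed_v_grid if treatment == "fixed" else (None,)
                    )
                    for fixed_v in v_grid:
                        yield kind, rep, float(d), treatment, fixed_v


def run_design(
    design: ExperimentDesign, per_patch: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Execute every design cell and return a tidy summary table.

    One row per cell with landscape-level statistics over the trailing
    ``record_window`` generations.  Individual cell failures are logged
    and flagged (``status='failed'``) rather than aborting the sweep.
    With ``per_patch=True`` a second table of per-patch statistics (one
    row per cell x patch) is also returned.
    """
    design.validate()
    landscapes: dict[tuple[str, int], LandscapeGraph] = {}
    rows = []
    patch_rows = []
    for kind, rep, d, treatment, fixed_v in _iter_cells(design):
        key_cols = {
            "scale": design.scale,
            "kind": kind,
            "rep": rep,
            "d": d,
            "treatment": treatment,
            "fixed_v": np.nan if fixed_v is None else float(fixed_v),
        }
        seed = cell_seed(design, kind, rep, d, treatment, fixed_v)
        try:
            lkey = (kind, rep)
            if lkey not in landscapes:
                landscapes[lkey] = make_landscape(design, kind, rep)
            g = landscapes[lkey]
            params = _cell_params(design, d, treatment, fixed_v)
            result = run(
                g,
                params,
                seed=seed,
                init=design.init,
                record_window=design.record_window,
            )
            pstats = vstats.patch_statistics(result, g, window=design.record_window)
            ev = vstats.evolved_virulence(result, persisted_only=True)
            rows.append(
                {
                    **key_cols,
                    "seed": seed,
                    "status": "ok",
                    "parasite_extinct": result.parasite_extinct,
                    "parasite_extinction_time": result.parasite_extinction_time,
                    "host_extinct": result.host_extinct,
                    "evolved_virulence": ev,
                    "relatedness": vstats.landscape_relatedness(
                        result, window=design.record_window
                    ),
                    "prevalence": float(pstats["prevalence"].mean()),
                    "mean_infected": float(pstats["mean_infected"].mean()),
                    "mean_susceptible": float(pstats["mean_susceptible"].mean()),
                    "local_extinction": float(pstats["local_extinction"].mean()),
                }
            )
            if per_patch:
                pstats = pstats.assign(**key_cols, seed=seed)
                patch_rows.append(pstats)
            log.info(
                "cell kind=%s rep=%d d=%.3g treatment=%s fixed_v=%s done "
                "(evolved_v=%.4g, extinct=%s)",
                kind, rep, d, treatment, fixed_v, ev, result.parasite_extinct,
            )
        except Exception as exc:  # cell failures flagged, not fatal
            log.exception(
                "cell kind=%s rep=%d d=%.3g treatment=%s failed", kind, rep, d, treatment
            )
            rows.append(
                {**key_cols, "seed": seed, "status": f"failed: {exc}"}
            )
    summary = pd.DataFrame(rows)
    if per_patch:
        patches = (
            pd.concat(patch_rows, ignore_index=True) if patch_rows else pd.DataFrame()
        )
        return summary, patches
    return summary


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_FOCAL_PARAMS = dict(lambda0=4.0, alpha=0.01, beta_max=8.0, s=0.5, a=0.01)


def preset_fig1(scale: str = "desk", master_seed: int = 0) -> ExperimentDesign:
    """Dispersal-gradient comparison of evolving, kin-shuffled, and
    fixed-virulence (v=0.94) runs at the focal parameters, on terrestrial-
    like and river-like landscapes.

    ``full`` is the production design (1,000 landscape realizations per
    kind, T=2,500); ``desk`` is a scaled-down configuration (10
    realizations, T=1,000, coarse dispersal grid) for interactive use.
    """
    if scale == "full":
        return ExperimentDesign(
            landscape_kinds=("rgg", "ocn"),
            n_landscapes=1000,
            dispersal_grid=DEFAULT_D_GRID,
            treatments=("evolving", "shuffled", "fixed"),
            fixed_v_grid=(0.94,),
            T=2500,
            master_seed=master_seed,
            base_params=dict(_FOCAL_PARAMS),
            scale="full",
        )
    if scale == "desk":
        return ExperimentDesign(
            landscape_kinds=("rgg", "ocn"),
            n_landscapes=10,
            dispersal_grid=(0.05, 0.1, 0.3, 0.5, 0.7, 1.0),
            treatments=("evolving", "shuffled", "fixed"),
            fixed_v_grid=(0.94,),
            T=1000,
            master_seed=master_seed,
            base_params=dict(_FOCAL_PARAMS),
            scale="desk",
        )
    raise ValueError("scale must be 'full' or 'desk'")


def preset_fig3(scale: str = "desk", master_seed: int = 0) -> ExperimentDesign:
    """Degree-stratified ecological-consequence sweep: evolving vs. fixed
    virulence (v=0.94) at dispersal d = 0.1, 0.5, 1; run with
    ``per_patch=True`` to obtain the per-degree statistics."""
    if scale == "full":
        return ExperimentDesign(
            landscape_kinds=("rgg", "ocn"),
            n_landscapes=1000,
            dispersal_grid=(0.1, 0.5, 1.0),
            treatments=("evolving", "fixed"),
            fixed_v_grid=(0.94,),
            T=2500,
            master_seed=master_seed,
            base_params=dict(_FOCAL_PARAMS),
            scale="full",
        )
    if scale == "desk":
        return ExperimentDesign(
            landscape_kinds=("rgg", "ocn"),
            n_landscapes=10,
            dispersal_grid=(0.1, 0.5, 1.0),
            treatments=("evolving", "fixed"),
            fixed_v_grid=(0.94,),
            T=1000,
            master_seed=master_seed,
            base_params=dict(_FOCAL_PARAMS),
            scale="desk",
        )
    raise ValueError("scale must be 'full' or 'desk'")
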