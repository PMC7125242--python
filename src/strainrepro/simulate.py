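"""Synthetic study generator: two observers, two replicates, three states.

Each generated segmental reading decomposes additively as

    value = mu[state, component]            population mean of the cell
          + A[animal, state, component]     between-animal effect, N(0, tau^2)
          + S[animal, segment, ...]         segment offset, N(0, segment_sd^2),
                                            centred within each animal so the
                                            16-segment mean is unaffected
          + bias[observer, ...]             additive observer bias
          + e[animal, observer, replicate]  analysis-session error, N(0, eps^2)

The session error is drawn once per analysis session — one observer
re-running the tracking for one animal/state/component — and shared across
that session's 16 segments, modelling the fact that contour placement
perturbs all segmental values of a session together.  Replicates of the same
observer share A and S and differ only in the session error (re-analysis of
the same images).  All draws come from a single numpy Generator seeded once
per call, so identical seeds give byte-identical datasets.

Default parameters reproduce the modelled study's conditions: 10 animals,
states BL/Dob/Ver, per-cell means and between-animal SDs from the published
per-state strain summaries, observer-2 biases equal to the published
inter-observer mean differences (negated, since the bias is on observer 2
and differences are observer1 - observer2), and session-error SDs backed out
of the published inter-observer difference SDs as eps = sd_diff / sqrt(2)
(difference of two independent equal-noise observers).
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from strainrepro import refvalues
from strainrepro.model import (
    DATASET_COLUMNS,
    GLOBAL_LABEL,
    N_SEGMENTS,
    Component,
    State,
)

_LABEL_TO_COMPONENT = {label: comp for comp, label in GLOBAL_LABEL.items()}


class CellParams(BaseModel):
    """Population mean and between-animal SD of one (state, component) cell."""

    mu: float
    tau: float = Field(ge=0.0)


class ObserverSpec(BaseModel):
    """One observer: additive bias (optionally per cell) and optional noise override."""

    id: str
    bias: float = 0.0
    bias_by_cell: dict[State, dict[Component, float]] = Field(default_factory=dict)
    noise_sd: Optional[float] = Field(default=None, ge=0.0)


def _default_cells() -> dict[State, dict[Component, CellParams]]:
    cells: dict[State, dict[Component, CellParams]] = {}
    for row in refvalues.STRAIN_SUMMARY.itertuples(index=False):
        comp = _LABEL_TO_COMPONENT[row.label]
        cells.setdefault(State(row.state), {})[comp] = CellParams(
            mu=float(row.first_mean), tau=float(row.first_sd)
        )
    return cells


def _default_observers() -> list[ObserverSpec]:
    inter = refvalues.AGREEMENT_SUMMARY
    inter = inter[inter["comparison"] == "inter_observer"]
    bias2: dict[State, dict[Component, float]] = {}
    for row in inter.itertuples(index=False):
        comp = _LABEL_TO_COMPONENT[row.label]
        # difference = observer1 - observer2, so observer2 carries -mean_diff
        bias2.setdefault(State(row.state), {})[comp] = -float(row.mean_diff)
    return [
        ObserverSpec(id="obs1"),
        ObserverSpec(id="obs2", bias_by_cell=bias2),
    ]


def _default_noise() -> dict[State, dict[Component, float]]:
    inter = refvalues.AGREEMENT_SUMMARY
    inter = inter[inter["comparison"] == "inter_observer"]
    eps: dict[State, dict[Component, float]] = {}
    for row in inter.itertuples(index=False):
        comp = _LABEL_TO_COMPONENT[row.label]
        eps.setdefault(State(row.state), {})[comp] = float(row.sd_diff) / np.sqrt(2.0)
    return eps


class GeneratorConfig(BaseModel):
    """Full specification of a synthetic study dataset.

    Defaults emulate the modelled study design: n = 10 animals, three
    inotropic states, three strain components, 16 segments, two observers,
    two replicates.
    """

    n_animals: int = Field(default=10, ge=2)
    states: list[State] = Field(default_factory=lambda: list(State))
    components: list[Component] = Field(default_factory=lambda: list(Component))
    cells: dict[State, dict[Component, CellParams]] = Field(default_factory=_default_cells)
    observers: list[ObserverSpec] = Field(default_factory=_default_observers)
    noise_sd: float = Field(default=2.0, ge=0.0)
    noise_sd_by_cell: dict[State, dict[Component, float]] = Field(
        default_factory=_default_noise
    )
    segment_sd: float = Field(default=3.0, ge=0.0)
    n_replicates: int = Field(default=2, ge=1)
    seed: int = Field(default=0, ge=0)

    @field_validator("states", "components", "observers")
    @classmethod
    def _non_empty_unique(cls, v):
        if not v:
            raise ValueError("must not be empty")
        keys = [getattr(item, "id", item) for item in v]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate entries: {keys}")
        return v

    @model_validator(mode="after")
    def _cells_cover_design(self):
        for state in self.states:
            for comp in self.components:
                if comp not in self.cells.get(state, {}):
                    raise ValueError(f"cells missing ({state.value}, {comp.value})")
        for state_map in self.noise_sd_by_cell.values():
            for eps in state_map.values():
                if eps < 0:
                    raise ValueError("noise SD must be >= 0")
        return self

    def cell_noise(self, observer: ObserverSpec, state: State, comp: Component) -> float:
        if observer.noise_sd is not None:
            return observer.noise_sd
        return self.noise_sd_by_cell.get(state, {}).get(comp, self.noise_sd)

    def cell_bias(self, observer: ObserverSpec, state: State, comp: Component) -> float:
        return observer.bias_by_cell.get(state, {}).get(comp, observer.bias)

    def n_records(self) -> int:
        return (self.n_animals * len(self.states) * len(self.components)
                * N_SEGMENTS * len(self.observers) * self.n_replicates)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        return cls.model_validate(json.loads(text))

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def preset_paper() -> GeneratorConfig:
    """The configuration emulating the modelled study's printed conditions."""
    return GeneratorConfig()


def generate(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one complete synthetic dataset as a long-format DataFrame.

    ``seed`` overrides ``config.seed``.  The draw order (states, components,
    then animal effects, segment offsets, and session errors per
    observer/replicate) is fixed, so a given seed yields a byte-identical
    dataset.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_animals
    width = max(2, len(str(n)))
    animals = np.array([f"A{i + 1:0{width}d}" for i in range(n)])
    segments = np.arange(1, N_SEGMENTS + 1)

    blocks = []
    for state in config.states:
        for comp in config.components:
            cell = config.cells[state][comp]
            a_eff = rng.normal(0.0, cell.tau, size=n)
            s_eff = rng.normal(0.0, config.segment_sd, size=(n, N_SEGMENTS))
            s_eff -= s_eff.mean(axis=1, keepdims=True)
            base = cell.mu + a_eff[:, None] + s_eff  # (n, 16)
            for obs in config.observers:
                bias = config.cell_bias(obs, state, comp)
                eps = config.cell_noise(obs, state, comp)
                for rep in range(1, config.n_replicates + 1):
                    e = rng.normal(0.0, eps, size=n)
                    values = base + bias + e[:, None]
                    blocks.append(pd.DataFrame({
                        "animal_id": np.repeat(animals, N_SEGMENTS),
                        "state": state.value,
                        "component": comp.value,
                        "segment_id": np.tile(segments, n),
                        "observer_id": obs.id,
                        "replicate": rep,
                        "value": values.ravel(),
                    }))
    df = pd.concat(blocks, ignore_index=True)[DATASET_COLUMNS]
    assert len(df) == config.n_records()
    return df


def dataset_manifest(config: GeneratorConfig, df: pd.DataFrame,
                     seed: int | None = None) -> dict:
    """Provenance record for a generated dataset."""
    from strainrepro import __version__

    return {
        "seed": config.seed if seed is None else seed,
        "config_hash": config.config_hash(),
        "n_records": int(len(df)),
        "package_version": __version__,
    }
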