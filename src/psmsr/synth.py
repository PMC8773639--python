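"""Synthetic live-imaging growth datasets.

Emulates the structure of a two-channel (red = sensitive-seeded, green =
tolerant-seeded) live-cell imaging study: monotypic and heterotypic
cultures at several seeding ratios, counts sampled every 2 h over 144 h,
with multiplicative lognormal count noise.  The default full design
produces on the order of 2900 data points, matching the size of the
growth dataset the model was calibrated on; ground-truth parameters
default to the published co-culture estimates so the generated data are
maximally faithful to the fitted system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import GrowthDataset
from .model import LineageState
from .params import DRUG_PRESETS, PRESETS, DrugParams, PhenotypeParams, params_to_config
from .simulate import DoseSchedule, SeedingDesign, integrate

__all__ = ["NoiseModel", "ConditionSpec", "StudyDesign", "generate_dataset", "make_fixture", "FIXTURES"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise on counts.

    ``lognormal`` multiplies each count by exp(sigma * z), z ~ N(0, 1) —
    unbiased on the log scale, preserving positivity and the
    scale-heterogeneity of imaging counts.  ``none`` returns the exact
    model counts.
    """

    kind: str = "lognormal"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition of a study.

    ``kind`` is ``monotypic-red``, ``monotypic-green`` or ``heterotypic``;
    monotypic wells seed a single channel (the panel's ratios are ignored
    and the whole inoculum goes into one line).
    """

    name: str
    params: PhenotypeParams
    kind: str = "heterotypic"
    drug: DrugParams | None = None
    schedule: DoseSchedule | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("heterotypic", "monotypic-red", "monotypic-green"):
            raise ValueError(f"unknown condition kind {self.kind!r}")


def _default_conditions() -> tuple[ConditionSpec, ...]:
    """Monotypic red/green plus the two heterotypic cohabitation histories.

    The published parameter table covers the heterotypic conditions; the
    monotypic wells reuse the immediate-mix co-culture estimates as
    generating truth (only one lineage is seeded, so cross-lineage
    structure is absent from those series by construction).
    """
    return (
        ConditionSpec("monotypic-red", PRESETS["heterotypic"], "monotypic-red"),
        ConditionSpec("monotypic-green", PRESETS["heterotypic"], "monotypic-green"),
        ConditionSpec("heterotypic-12h", PRESETS["heterotypic"], "heterotypic"),
        ConditionSpec("heterotypic-3wk", PRESETS["heterotypic-3wk"], "heterotypic"),
    )


@dataclass(frozen=True)
class StudyDesign:
    """Full synthetic study: conditions x seeding panel x replicates."""

    conditions: tuple = field(default_factory=_default_conditions)
    panel: SeedingDesign = field(default_factory=SeedingDesign)
    replicates: int = 2
    coupling: str = "linear"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def generate_dataset(
    design: StudyDesign | None = None, noise: NoiseModel | None = None
) -> GrowthDataset:
    """Simulate a study design and apply measurement noise.

    Returns a tidy :class:`~psmsr.fitting.GrowthDataset`; per-condition
    metadata records the generating parameters (``truth``), the schedule
    and the drug flag, so recovery experiments can compare against ground
    truth without bookkeeping on the caller's side.  Deterministic for a
    fixed ``noise.seed``.
    """
    design = design or StudyDesign()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    panel = design.panel
    times = panel.times
    rows = []
    conditions_meta: dict = {}
    for spec in design.conditions:
        truth = params_to_config(spec.params, spec.drug, coupling=design.coupling)
        seeding: dict = {}
        conditions_meta[spec.name] = {
            "drug": spec.drug is not None,
            "schedule": spec.schedule,
            "truth": truth,
            "kind": spec.kind,
            # true seeded counts per series: known by design in a plated
            # experiment, used by the fitter as exact initial conditions
            "seeding": seeding,
        }
        if spec.kind == "heterotypic":
            seedings = [
                (r, panel.initial_state(r).Rs, panel.initial_state(r).Gt)
                for r in panel.ratios
            ]
        elif spec.kind == "monotypic-red":
            seedings = [((1, 0), panel.total_cells, 0.0)]
        else:
            seedings = [((0, 1), 0.0, panel.total_cells)]
        for ratio, red0, green0 in seedings:
            init = LineageState.from_seeding(red=red0, green=green0)
            traj = integrate(
                spec.params, spec.drug, init, spec.schedule, times,
                coupling=design.coupling, label=spec.name, ratio=tuple(ratio),
            )
            for rep in range(1, design.replicates + 1):
                seeding[(f"{ratio[0]}:{ratio[1]}", rep)] = (red0, green0)
                for channel, series in (("red", traj.red), ("green", traj.green)):
                    if series[0] <= 0:
                        continue  # unseeded channel in monotypic wells
                    counts = series.copy()
                    if noise.kind == "lognormal" and noise.sigma > 0:
                        counts = counts * np.exp(
                            noise.sigma * rng.standard_normal(counts.size)
                        )
                    rows.append(
                        pd.DataFrame(
                            {
                                "condition": spec.name,
                                "ratio": f"{ratio[0]}:{ratio[1]}",
                                "time_h": traj.times_h,
                                "channel": channel,
                                "count": counts,
                                "replicate": rep,
                            }
                        )
                    )
    frame = pd.concat(rows, ignore_index=True)
    return GrowthDataset(frame, conditions_meta)


# ---------------------------------------------------------------------------
# small registered fixtures for fast tests
# ---------------------------------------------------------------------------

def _tiny_heterotypic() -> StudyDesign:
    # 2 ratios x 13 timepoints x 2 channels = 52 records
    panel = SeedingDesign(
        total_cells=5000.0, ratios=((1, 1), (4, 1)),
        duration_days=6.0, sample_every_h=12.0,
    )
    return StudyDesign(
        conditions=(ConditionSpec("heterotypic-12h", PRESETS["heterotypic"]),),
        panel=panel,
        replicates=1,
    )


def _drug_panel() -> StudyDesign:
    # continuous and intermittent cisplatin on the locked drug-condition
    # parameters: 2 conditions x 2 ratios x 13 timepoints x 2 channels
    panel = SeedingDesign(
        total_cells=5000.0, ratios=((1, 1), (4, 1)),
        duration_days=6.0, sample_every_h=12.0,
    )
    p = PRESETS["heterotypic-cisplatin"]
    d = DRUG_PRESETS["heterotypic-cisplatin"]
    return StudyDesign(
        conditions=(
            ConditionSpec(
                "cisplatin-continuous", p, "heterotypic", drug=d,
                schedule=DoseSchedule.continuous(5.0, 6.0),
            ),
            ConditionSpec(
                "cisplatin-intermittent", p, "heterotypic", drug=d,
                schedule=DoseSchedule.intermittent_1(5.0),
            ),
        ),
        panel=panel,
        replicates=1,
    )


FIXTURES = {"tiny-heterotypic": _tiny_heterotypic, "drug-panel": _drug_panel}


def make_fixture(name: str, *, sigma: float = 0.05, seed: int = 0) -> GrowthDataset:
    """Generate a small registered dataset (<= 200 records) for fast tests.

    The generating parameters travel with the dataset in
    ``conditions[...]["truth"]``.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    design = FIXTURES[name]()
    return generate_dataset(design, NoiseModel("lognormal" if sigma > 0 else "none", sigma, seed))
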