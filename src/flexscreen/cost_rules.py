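"""Treatment and screening cost rules.

Treatment costs are age-band and stage specific, split into three phase
tables (all in euros, specialized-care treatment costs only):

* ``C1`` — first year after diagnosis,
* ``C2`` — each of years 2-5 after diagnosis,
* ``C3`` — the last year before a breast-cancer death.

The accumulation rules, for a patient dying ``n`` years after diagnosis
(``n`` is an inclusive count of calendar years entered, so a death within the
first year is ``n = 1``):

other-cause death (d = 2)::

    C_n = C1 + (n - 1) C2     for 1 <= n <= 5
    C_n = C1 + 4 C2           for n > 5

breast-cancer death (d = 1)::

    C_n = (n - 1) C1 + C3             for n in {1, 2}
    C_n = C1 + (n - 2) C2 + C3        for n in {3, 4, 5}
    C_n = C1 + 4 C2 + C3              for n > 5

The d = 1 rule at ``n = 2`` (``C1 + C3``, no ``C2`` term) is deliberately not
harmonized with the d = 2 rule at ``n = 2`` (``C1 + C2``): the published cost
convention is reproduced exactly as stated.

Treatment beyond year 5 accrues nothing (a conservative convention; real
treatment and follow-up often runs 5-10 years).

The packaged default tables cover 7 age bands x 5 stages; the screening cost
is a flat 30 euros per invitee per screened round.  Costs are indexed by age
at diagnosis throughout treatment, not attained age.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_core import AgeGrid, N_STAGES, ValidationError

__all__ = [
    "AGE_BANDS",
    "BAND_LABELS",
    "CostModel",
    "band_of",
    "accumulate_cost",
    "build_cost_tensor",
    "load_default_cost_model",
]

#: (lower age, upper age inclusive); the last band is open-ended.
AGE_BANDS = ((46, 49), (50, 54), (55, 59), (60, 64), (65, 69), (70, 74), (75, None))
BAND_LABELS = ("46-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75+")

BC_DEATH, OTHER_DEATH = 1, 2

_DATA_FILES = {
    "c1": "treatment_cost_first_year.csv",
    "c2": "treatment_cost_years_2_to_5.csv",
    "c3": "treatment_cost_final_year.csv",
}


def band_of(age: int) -> int:
    """Index of the cost age band containing ``age`` (total mapping for >= 46)."""
    if age < AGE_BANDS[0][0]:
        raise ValidationError(f"age {age} below the first cost band")
    for i, (lo, hi) in enumerate(AGE_BANDS):
        if hi is None or age <= hi:
            if age >= lo:
                return i
    raise AssertionError("unreachable: bands cover all ages >= 46")


@dataclass(frozen=True)
class CostModel:
    """Phase cost tables (euros) plus the unit screening cost per invitee.

    ``c1``, ``c2``, ``c3`` are ``(n_bands, n_stages)`` arrays, rows in
    :data:`BAND_LABELS` order, columns stages 0..4.
    """

    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    screening_unit_cost: float = 30.0

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def violations(self) -> list[str]:
        out: list[str] = []
        shape = (len(AGE_BANDS), N_STAGES)
        for name in ("c1", "c2", "c3"):
            arr = getattr(self, name)
            if arr.shape != shape:
                out.append(f"cost table {name}: expected shape {shape}, got {arr.shape}")
                continue
            if np.isnan(arr).any():
                b, k = np.argwhere(np.isnan(arr))[0]
                out.append(f"cost table {name}: missing cell (band {BAND_LABELS[b]}, stage {k})")
            if (arr < 0).any():
                b, k = np.argwhere(arr < 0)[0]
                out.append(f"cost table {name}: negative cell (band {BAND_LABELS[b]}, stage {k})")
        if self.screening_unit_cost < 0:
            out.append(f"screening_unit_cost must be >= 0, got {self.screening_unit_cost!r}")
        return out

    def scale_treatment(self, alpha: float) -> "CostModel":
        """Multiply every treatment cell by ``alpha``; screening cost untouched."""
        if alpha <= 0:
            raise ValidationError(f"cost scale factor must be positive, got {alpha!r}")
        return replace(
            self, c1=self.c1 * alpha, c2=self.c2 * alpha, c3=self.c3 * alpha
        )

    def to_frames(self) -> dict[str, pd.DataFrame]:
        cols = [f"stage_{k}" for k in range(N_STAGES)]
        return {
            name: pd.DataFrame(getattr(self, name), index=list(BAND_LABELS), columns=cols)
            .rename_axis("band")
            for name in ("c1", "c2", "c3")
        }

    @classmethod
    def from_frames(
        cls,
        c1: pd.DataFrame,
        c2: pd.DataFrame,
        c3: pd.DataFrame,
        screening_unit_cost: float = 30.0,
    ) -> "CostModel":
        tables = []
        for name, df in (("c1", c1), ("c2", c2), ("c3", c3)):
            df = df.set_index("band") if "band" in df.columns else df
            if list(df.index) != list(BAND_LABELS):
                raise ValidationError(
                    f"cost table {name}: bands must be {list(BAND_LABELS)}, got {list(df.index)}"
                )
            cols = [f"stage_{k}" for k in range(N_STAGES)]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValidationError(f"cost table {name}: missing columns {missing}")
            tables.append(df[cols].to_numpy(dtype=float))
        return cls(*tables, screening_unit_cost=screening_unit_cost)


def load_default_cost_model(screening_unit_cost: float = 30.0) -> CostModel:
    """Load the packaged Finnish age/stage treatment-cost tables."""
    frames = {}
    root = importlib.resources.files("flexscreen") / "data"
    for name, fname in _DATA_FILES.items():
        with (root / fname).open("r", encoding="utf-8") as fh:
            frames[name] = pd.read_csv(fh)
    return CostModel.from_frames(
        frames["c1"], frames["c2"], frames["c3"], screening_unit_cost=screening_unit_cost
    )


def accumulate_cost(model: CostModel, n: int, d: int, band: int, k: int) -> float:
    """Total treatment cost (euros) for a death ``n`` years after diagnosis.

    ``d`` is the cause (1 = breast cancer, 2 = other), ``band`` the cost age
    band at diagnosis, ``k`` the diagnosed stage 0..4.
    """
    if n < 1:
        raise ValidationError(f"cost year index n must be >= 1, got {n}")
    if d not in (BC_DEATH, OTHER_DEATH):
        raise ValidationError(f"cause of death must be 1 or 2, got {d}")
    if not 0 <= k < N_STAGES:
        raise ValidationError(f"stage must be 0..{N_STAGES - 1}, got {k}")
    c1 = float(model.c1[band, k])
    c2 = float(model.c2[band, k])
    c3 = float(model.c3[band, k])
    if d == OTHER_DEATH:
        return c1 + (min(n, 5) - 1) * c2
    if n <= 2:
        return (n - 1) * c1 + c3
    return c1 + min(n - 2, 4) * c2 + c3


def build_cost_tensor(model: CostModel, grid: AgeGrid, n_t: int) -> np.ndarray:
    """Dense cost array ``C[j, k, t, d_index]`` for diagnosed stages.

    ``d_index`` 0 is breast-cancer death, 1 other-cause death, matching the
    cause axis of the joint survival law.  The survival time ``t`` (whole
    years lived after diagnosis) maps to the cost year count as
    ``n = t + 1``: a death within the first year (t = 0) is n = 1.  The
    cancer-free state carries no treatment cost and is handled by callers.
    """
    problems = model.violations()
    if problems:
        raise ValidationError(problems)
    tensor = np.empty((grid.n_groups, N_STAGES, n_t, 2))
    for j in range(grid.n_groups):
        b = band_of(grid.lower_age(j))
        for k in range(N_STAGES):
            for t in range(n_t):
                n = t + 1
                tensor[j, k, t, 0] = accumulate_cost(model, n, BC_DEATH, b, k)
                tensor[j, k, t, 1] = accumulate_cost(model, n, OTHER_DEATH, b, k)
    return tensor
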