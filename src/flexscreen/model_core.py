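"""Core domain types for the stage-distribution screening model.

The model follows a cohort of women through biennial screening rounds.  Age
groups are two years wide; group ``j`` (0-based here) covers ages
``46 + 2j`` to ``47 + 2j``, and nobody survives past age 100.  At every round
an invitee is observed in exactly one state ``k``:

* ``k = -1`` — no breast cancer,
* ``k = 0..4`` — diagnosed at stage Unknown / Localized / Regional /
  Distant-or-adjacent / In situ.

The state distribution ``mu_{j,h}(k)`` under a screening policy ``h`` factors
into an incidence rate ``iota(j, h(j)) = P(X != -1)`` and a conditional stage
distribution ``q(j, h(j), k) = P(X = k | X != -1)``.  Survival after
observation in state ``k`` is a discrete law ``lam_{j,k}(t)`` over whole years
``t``, and for diagnosed states a joint law ``pi_{j,k}(t, d)`` additionally
records the cause of death (``d = 1`` breast cancer, ``d = 2`` other).

Probabilities here are at the invitee (invited-population) level: screening
participation is assumed constant across age groups and is folded into the
incidence rates and stage distributions rather than modelled as a separate
parameter.

Array layout conventions used throughout the package:

* stage axis of ``mu`` and ``lam`` has length ``K + 2`` with index 0 for
  ``k = -1`` and index ``k + 1`` for diagnosed stages;
* ``q`` and ``pi`` carry diagnosed stages only (length ``K + 1``, index = k);
* screening-status axis has index 0 = NS (not screened), 1 = S (screened);
* time axis covers ``t = 0 .. horizon_age - start_age`` for every group
  (rows for a group must be zero beyond its own ``t_max``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NO_CANCER",
    "N_STAGES",
    "STAGE_LABELS",
    "PROB_TOL",
    "ValidationError",
    "AgeGrid",
    "PolicyVector",
    "IncidenceSchedule",
    "ConditionalStageDistribution",
    "StateDistribution",
    "SurvivalLaw",
    "CauseJointLaw",
    "ModelInputs",
    "compose_state_distribution",
    "decompose_state_distribution",
    "expected_remaining_years",
    "validate_inputs",
]

NO_CANCER = -1
#: number of diagnosed stages (k = 0..4)
N_STAGES = 5
STAGE_LABELS = {
    -1: "no cancer",
    0: "unknown",
    1: "localized",
    2: "regional",
    3: "distant/adjacent",
    4: "in situ",
}

#: tolerance for probability-sum checks; inputs violating it are rejected,
#: never silently renormalized (renormalizing would mask data-entry errors).
PROB_TOL = 1e-9

NOT_SCREENED, SCREENED = 0, 1
STATUS_LABELS = ("NS", "S")


class ValidationError(ValueError):
    """Raised when model inputs violate a structural invariant.

    ``violations`` holds every violation found (operations that validate
    aggregate all failures instead of stopping at the first).
    """

    def __init__(self, violations: Sequence[str] | str):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class AgeGrid:
    """Two-year age groups from ``start_age`` up to a hard survival horizon.

    Group ``j`` (0-based) covers ages ``start_age + 2j`` .. ``start_age +
    2j + 1``; the default grid starts at 46 and has 27 groups, ending at
    ages 98-99.  No survival law may put mass past ``horizon_age`` (100).
    """

    n_groups: int
    start_age: int = 46
    horizon_age: int = 100

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValidationError("AgeGrid: n_groups must be >= 1")
        if self.lower_age(self.n_groups - 1) + 1 >= self.horizon_age:
            raise ValidationError(
                "AgeGrid: last age group extends past the survival horizon"
            )

    def lower_age(self, j: int) -> int:
        return self.start_age + 2 * j

    def t_max(self, j: int) -> int:
        """Largest number of whole years a member of group ``j`` can live."""
        return self.horizon_age - self.lower_age(j)

    @property
    def n_t(self) -> int:
        """Length of the common time axis (``t = 0 .. t_max(0)``)."""
        return self.t_max(0) + 1

    def group_of_age(self, age: int) -> int:
        j = (age - self.start_age) // 2
        if not 0 <= j < self.n_groups:
            raise ValidationError(f"age {age} outside the grid")
        return j

    def ages(self) -> list[tuple[int, int]]:
        return [(self.lower_age(j), self.lower_age(j) + 1) for j in range(self.n_groups)]


@dataclass(frozen=True)
class PolicyVector:
    """Screening policy: one flag per age group, ``"S"`` or ``"NS"``."""

    flags: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [f for f in self.flags if f not in STATUS_LABELS]
        if bad:
            raise ValidationError(f"policy flags must be 'S'/'NS', got {bad!r}")

    @property
    def n_groups(self) -> int:
        return len(self.flags)

    def screened(self, j: int) -> bool:
        return self.flags[j] == "S"

    def status_index(self, j: int) -> int:
        return SCREENED if self.screened(j) else NOT_SCREENED

    def status_indices(self) -> np.ndarray:
        return np.array([self.status_index(j) for j in range(self.n_groups)])

    def with_screened(self, groups: Iterable[int]) -> "PolicyVector":
        flags = list(self.flags)
        for j in groups:
            flags[j] = "S"
        return PolicyVector(tuple(flags))

    @classmethod
    def no_screening(cls, n_groups: int) -> "PolicyVector":
        return cls(("NS",) * n_groups)

    @classmethod
    def all_screening(cls, n_groups: int) -> "PolicyVector":
        return cls(("S",) * n_groups)

    @classmethod
    def screening_ages(cls, grid: AgeGrid, first_age: int, last_age: int) -> "PolicyVector":
        """Screen every group fully contained in ``[first_age, last_age]``."""
        flags = tuple(
            "S" if first_age <= grid.lower_age(j) and grid.lower_age(j) + 1 <= last_age
            else "NS"
            for j in range(grid.n_groups)
        )
        return cls(flags)

    def label(self, grid: AgeGrid) -> str:
        """Human-readable span of screened ages, e.g. ``'50-69 yr'``."""
        screened = [j for j in range(self.n_groups) if self.screened(j)]
        if not screened:
            return "no screening"
        return f"{grid.lower_age(screened[0])}-{grid.lower_age(screened[-1]) + 1} yr"


@dataclass(frozen=True)
class IncidenceSchedule:
    """Per-(group, screening status) diagnosis probability ``P(X != -1)``.

    ``iota`` has shape ``(n_groups, 2)``; column 0 is NS, column 1 is S.
    Each entry is the probability that an invitee of the group is diagnosed
    (any stage) during the two-year interval.
    """

    iota: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "iota", np.asarray(self.iota, dtype=float))

    @property
    def n_groups(self) -> int:
        return self.iota.shape[0]

    def rate(self, j: int, status: int) -> float:
        return float(self.iota[j, status])

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.iota.ndim != 2 or self.iota.shape[1] != 2:
            return [f"incidence: expected shape (J, 2), got {self.iota.shape}"]
        bad = np.argwhere((self.iota < 0) | (self.iota > 1))
        for j, s in bad:
            out.append(
                f"incidence: iota out of [0, 1] at group {j} "
                f"status {STATUS_LABELS[s]} ({self.iota[j, s]!r})"
            )
        return out


@dataclass(frozen=True)
class ConditionalStageDistribution:
    """Stage law given diagnosis: ``q[j, status, k] = P(X = k | X != -1)``."""

    q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))

    @property
    def n_groups(self) -> int:
        return self.q.shape[0]

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.q.ndim != 3 or self.q.shape[1:] != (2, N_STAGES):
            return [f"stages: expected shape (J, 2, {N_STAGES}), got {self.q.shape}"]
        for j, s in np.argwhere((self.q < 0).any(axis=2)):
            k = int(np.argwhere(self.q[j, s] < 0)[0, 0])
            out.append(
                f"stages: negative q at group {j} status {STATUS_LABELS[s]} stage {k}"
            )
        sums = self.q.sum(axis=2)
        for j, s in np.argwhere(np.abs(sums - 1.0) > PROB_TOL):
            out.append(
                f"stages: q row does not sum to 1 at group {j} "
                f"status {STATUS_LABELS[s]} (sum {sums[j, s]!r})"
            )
        return out


@dataclass(frozen=True)
class StateDistribution:
    """Unconditional state law ``mu[j, k]`` under one policy.

    Shape ``(n_groups, N_STAGES + 1)``; column 0 is ``k = -1``, column
    ``k + 1`` is diagnosed stage ``k``.
    """

    mu: np.ndarray
    policy: PolicyVector

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))

    @property
    def n_groups(self) -> int:
        return self.mu.shape[0]

    def no_cancer(self, j: int) -> float:
        return float(self.mu[j, 0])

    def diagnosed(self, j: int) -> np.ndarray:
        """Probabilities of stages 0..K (index = stage)."""
        return self.mu[j, 1:]

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.mu.ndim != 2 or self.mu.shape[1] != N_STAGES + 1:
            return [f"mu: expected shape (J, {N_STAGES + 1}), got {self.mu.shape}"]
        if (self.mu < 0).any():
            j, c = np.argwhere(self.mu < 0)[0]
            out.append(f"mu: negative probability at group {j} stage {int(c) - 1}")
        sums = self.mu.sum(axis=1)
        for (j,) in np.argwhere(np.abs(sums - 1.0) > PROB_TOL):
            out.append(f"mu: row {j} sums to {sums[j]!r}, not 1")
        return out


@dataclass(frozen=True)
class SurvivalLaw:
    """Discrete survival mass ``lam[j, k_index, t] = P(T_{j,k} = t)``.

    ``k_index`` 0 is the cancer-free state ``k = -1`` (background mortality of
    women without breast cancer); ``k_index = k + 1`` the diagnosed stages.
    ``t`` counts whole years lived after observation at round ``j``.  Mass
    beyond a group's ``t_max`` must be zero (the 100-year horizon): rows are
    checked, never truncated.
    """

    lam: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lam", np.asarray(self.lam, dtype=float))

    @property
    def n_groups(self) -> int:
        return self.lam.shape[0]

    @property
    def n_t(self) -> int:
        return self.lam.shape[2]

    def mass(self, j: int, k: int) -> np.ndarray:
        """Survival mass for state ``k`` (−1..K) at group ``j``."""
        return self.lam[j, k + 1]

    def violations(self, grid: AgeGrid | None = None) -> list[str]:
        out: list[str] = []
        if self.lam.ndim != 3 or self.lam.shape[1] != N_STAGES + 1:
            return [f"survival: expected shape (J, {N_STAGES + 1}, T), got {self.lam.shape}"]
        if (self.lam < 0).any():
            j, ki, t = np.argwhere(self.lam < 0)[0]
            out.append(
                f"survival: negative mass at group {j} stage {int(ki) - 1} t={t}"
            )
        sums = self.lam.sum(axis=2)
        for j, ki in np.argwhere(np.abs(sums - 1.0) > PROB_TOL):
            out.append(
                f"survival: lam row does not sum to 1 at group {j} "
                f"stage {int(ki) - 1} (sum {sums[j, ki]!r})"
            )
        if grid is not None:
            for j in range(min(self.n_groups, grid.n_groups)):
                tail = self.lam[j, :, grid.t_max(j) + 1 :]
                if tail.size and (tail != 0).any():
                    out.append(
                        f"survival: group {j} has mass past t_max={grid.t_max(j)} "
                        "(violates the 100-year horizon)"
                    )
        return out


@dataclass(frozen=True)
class CauseJointLaw:
    """Joint law ``pi[j, k, t, d_index] = P(T = t, D = d)`` for diagnosed k.

    ``d_index`` 0 is breast-cancer death (d = 1), 1 is other cause (d = 2).
    Marginalizing over cause must recover the survival law for every
    diagnosed stage.
    """

    pi: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))

    @property
    def n_groups(self) -> int:
        return self.pi.shape[0]

    def mass(self, j: int, k: int) -> np.ndarray:
        """Joint (t, d) mass for diagnosed stage ``k >= 0``; shape (T, 2)."""
        if k < 0:
            raise ValidationError("cause-of-death law is defined for diagnosed stages only")
        return self.pi[j, k]

    def bc_death_mass(self, j: int, k: int) -> np.ndarray:
        return self.pi[j, k, :, 0]

    def violations(self, survival: SurvivalLaw | None = None) -> list[str]:
        out: list[str] = []
        if self.pi.ndim != 4 or self.pi.shape[1] != N_STAGES or self.pi.shape[3] != 2:
            return [f"causes: expected shape (J, {N_STAGES}, T, 2), got {self.pi.shape}"]
        if (self.pi < 0).any():
            j, k, t, d = np.argwhere(self.pi < 0)[0]
            out.append(f"causes: negative mass at group {j} stage {k} t={t} d={int(d) + 1}")
        if survival is not None:
            marg = self.pi.sum(axis=3)
            lam_diag = survival.lam[:, 1:, :]
            bad = np.argwhere(np.abs(marg - lam_diag) > PROB_TOL)
            for j, k, t in bad[:20]:  # cap the report; one line per cell
                out.append(
                    f"causes: sum over d of pi != lam at group {j} stage {k} t={t} "
                    f"({marg[j, k, t]!r} vs {lam_diag[j, k, t]!r})"
                )
        return out


@dataclass(frozen=True)
class ModelInputs:
    """Complete parameter set for one cohort analysis.

    ``cost_model`` is a :class:`flexscreen.cost_rules.CostModel`; the type is
    not imported here to keep the dependency one-way.
    """

    age_grid: AgeGrid
    incidence: IncidenceSchedule
    stages: ConditionalStageDistribution
    survival: SurvivalLaw
    causes: CauseJointLaw
    cost_model: object
    n0: float = 100_000.0

    def replace(self, **kw) -> "ModelInputs":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compose_state_distribution(
    incidence: IncidenceSchedule,
    stages: ConditionalStageDistribution,
    policy: PolicyVector,
) -> StateDistribution:
    """Combine incidence and conditional stage law into the state law.

    ``mu(j, -1) = 1 - iota(j, h(j))`` and ``mu(j, k) = q(j, h(j), k) *
    iota(j, h(j))`` for diagnosed stages — the factorization of the state
    distribution into an incidence rate and a stage law given diagnosis.
    """
    problems = incidence.violations() + stages.violations()
    if incidence.n_groups != stages.n_groups:
        problems.append(
            f"incidence has {incidence.n_groups} groups but stages has {stages.n_groups}"
        )
    if policy.n_groups != incidence.n_groups:
        problems.append(
            f"policy has {policy.n_groups} groups but inputs have {incidence.n_groups}"
        )
    if problems:
        raise ValidationError(problems)

    idx = policy.status_indices()
    rows = np.arange(incidence.n_groups)
    iota_h = incidence.iota[rows, idx]  # (J,)
    q_h = stages.q[rows, idx, :]  # (J, K+1)
    mu = np.empty((incidence.n_groups, N_STAGES + 1))
    mu[:, 0] = 1.0 - iota_h
    mu[:, 1:] = q_h * iota_h[:, None]
    return StateDistribution(mu=mu, policy=policy)


def decompose_state_distribution(
    mu: StateDistribution,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover ``(iota_h, q_h)`` per group from a composed state law.

    Inverse of :func:`compose_state_distribution` along the policy's own
    status; only defined where ``iota > 0`` (q is unidentifiable otherwise).
    """
    iota = 1.0 - mu.mu[:, 0]
    if (iota <= 0).any():
        j = int(np.argwhere(iota <= 0)[0])
        raise ValidationError(f"cannot decompose: zero incidence at group {j}")
    q = mu.mu[:, 1:] / iota[:, None]
    return iota, q


def expected_remaining_years(lam_row: np.ndarray) -> float:
    """Mean of a discrete survival mass: ``E T = sum_t t * lam(t)``."""
    lam_row = np.asarray(lam_row, dtype=float)
    if abs(lam_row.sum() - 1.0) > PROB_TOL:
        raise ValidationError(
            f"survival mass sums to {lam_row.sum()!r}, not 1 — refusing to average"
        )
    if (lam_row < 0).any():
        raise ValidationError("survival mass has negative entries")
    return float(np.arange(lam_row.size) @ lam_row)


def validate_inputs(inputs: ModelInputs) -> list[str]:
    """Report every violated invariant; an empty list means valid.

    Never repairs anything: callers decide whether to raise.
    """
    grid = inputs.age_grid
    out: list[str] = []
    for comp in (inputs.incidence, inputs.stages):
        out.extend(comp.violations())
        if comp.n_groups != grid.n_groups:
            out.append(
                f"{type(comp).__name__}: {comp.n_groups} groups, grid has {grid.n_groups}"
            )
    out.extend(inputs.survival.violations(grid))
    if inputs.survival.n_groups != grid.n_groups:
        out.append(
            f"SurvivalLaw: {inputs.survival.n_groups} groups, grid has {grid.n_groups}"
        )
    if inputs.survival.n_t < grid.n_t:
        out.append(
            f"SurvivalLaw: time axis {inputs.survival.n_t} shorter than grid needs ({grid.n_t})"
        )
    out.extend(inputs.causes.violations(inputs.survival))
    if inputs.n0 <= 0:
        out.append(f"n0 must be positive, got {inputs.n0!r}")
    cm = inputs.cost_model
    if cm is None:
        out.append("cost_model is missing")
    else:
        out.extend(cm.violations())
    return out


def require_valid(inputs: ModelInputs) -> ModelInputs:
    """Raise :class:`ValidationError` listing all violations, or pass through."""
    problems = validate_inputs(inputs)
    if problems:
        raise ValidationError(problems)
    return inputs
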