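"""Simulated pre/post cohort measurement tables.

The generator inverts the statistical model the analysis assumes: each
measurement is a cell mean (group x time x region x layer) plus an optional
covariate contribution, a participant random intercept shared by all of
that participant's rows, and independent residual noise,

    value = mu(group, time, region, layer)
            + beta_age * (age - age_ref) + beta_bmi * (bmi - bmi_ref)
            + b_i + eps,     b_i ~ N(0, sd_intercept^2),  eps ~ N(0, sd_residual^2).

Tables are long format: one row per participant x time x region x layer,
matching the measurement tables the imaging arm produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

TIMES = ("pre", "post")

#: Typical load-bearing knee cartilage T2 cell means (ms) pre/post an acute
#: walking stimulus, for healthy adults and adults at risk of knee OA.
#: Keyed (group, time, region_name, layer).  Used as generator defaults.
REFERENCE_T2_MEANS: dict[tuple[str, str, str, str], float] = {}


def _fill_reference_means() -> None:
    sup = {
        # region: (healthy pre, healthy post, at-risk pre, at-risk post)
        "medial_femur": (55.75, 51.42, 54.80, 49.36),
        "medial_tibia": (50.94, 45.91, 52.47, 47.32),
        "lateral_femur": (53.01, 49.66, 53.35, 50.79),
        "lateral_tibia": (45.30, 42.44, 46.01, 43.97),
        "patella": (49.03, 46.88, 51.69, 48.82),
        "trochlea": (50.88, 49.14, 53.39, 52.93),
    }
    deep = {
        "medial_femur": (40.57, 38.37, 39.70, 38.09),
        "medial_tibia": (39.14, 38.19, 38.81, 38.66),
        "lateral_femur": (39.73, 38.69, 39.20, 38.32),
        "lateral_tibia": (35.76, 35.52, 36.01, 36.69),
        "patella": (38.81, 38.16, 40.31, 40.33),
        "trochlea": (46.65, 45.98, 48.39, 47.76),
    }
    for layer, table in (("superficial", sup), ("deep", deep)):
        for region, (h_pre, h_post, r_pre, r_post) in table.items():
            REFERENCE_T2_MEANS[("healthy", "pre", region, layer)] = h_pre
            REFERENCE_T2_MEANS[("healthy", "post", region, layer)] = h_post
            REFERENCE_T2_MEANS[("at-risk", "pre", region, layer)] = r_pre
            REFERENCE_T2_MEANS[("at-risk", "post", region, layer)] = r_post


_fill_reference_means()


@dataclass(frozen=True)
class CovariateSpec:
    """Per-participant covariate: sampled N(mean, sd), contributes
    ``coef * (x - mean)`` to every measurement so cell means stay at mu."""

    mean: float
    sd: float
    coef: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated pre/post cohort.

    ``cell_means`` maps (group, time, region, layer) to the true mean in
    the response units (ms for T2, mm for thickness).  Every (group, time)
    cell must cover every region x layer in scope.  Defaults reproduce a
    two-group (n=16 each) acute-loading T2 study with a participant
    random-intercept SD of 8 ms and residual SD of 2 ms.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"healthy": 16, "at-risk": 16}
    )
    cell_means: Mapping[tuple[str, str, str, str], float] = field(
        default_factory=lambda: dict(REFERENCE_T2_MEANS)
    )
    sd_intercept: float = 8.0
    sd_residual: float = 2.0
    age: CovariateSpec | None = None
    bmi: CovariateSpec | None = None

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("at least one group is required")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} is empty")
        if self.sd_intercept < 0 or self.sd_residual < 0:
            raise ValueError("variance components must be non-negative")
        cells = set(self.cell_means)
        rl = {(r, l) for (_, _, r, l) in cells}
        for g in self.group_sizes:
            for t in TIMES:
                for r, l in rl:
                    if (g, t, r, l) not in cells:
                        raise ValueError(
                            f"missing cell mean for ({g}, {t}, {r}, {l})"
                        )

    @property
    def region_layers(self) -> list[tuple[str, str]]:
        return sorted({(r, l) for (_, _, r, l) in self.cell_means})


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table from the generative model.

    Returns a long-format DataFrame with columns participant_id, group,
    time, region, layer, value, age, bmi.  The table is balanced: every
    participant has exactly one row per time x region x layer.  Same spec
    and seed give an identical table.
    """
    spec.validate()
    if seed is None:
        raise ValueError("a seed is required for reproducible cohort generation")
    rng = np.random.default_rng(seed)
    region_layers = spec.region_layers

    rows = []
    for group, n in spec.group_sizes.items():
        for i in range(n):
            pid = f"{group}-{i + 1:02d}"
            b = rng.normal(0.0, spec.sd_intercept)
            age = rng.normal(spec.age.mean, spec.age.sd) if spec.age else np.nan
            bmi = rng.normal(spec.bmi.mean, spec.bmi.sd) if spec.bmi else np.nan
            cov = 0.0
            if spec.age:
                cov += spec.age.coef * (age - spec.age.mean)
            if spec.bmi:
                cov += spec.bmi.coef * (bmi - spec.bmi.mean)
            for time in TIMES:
                for region, layer in region_layers:
                    mu = spec.cell_means[(group, time, region, layer)]
                    eps = rng.normal(0.0, spec.sd_residual)
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "time": time,
                            "region": region,
                            "layer": layer,
                            "value": mu + cov + b + eps,
                            "age": age,
                            "bmi": bmi,
                        }
                    )
    return pd.DataFrame(rows)


def balanced_table(
    cell_means: Mapping[tuple[str, str, str, str], float],
    n_per_group: int = 16,
    intercept_spread: float = 5.0,
    residual_spread: float = 0.5,
) -> pd.DataFrame:
    """Deterministic balanced table whose cell means are met *exactly*.

    Worked-example companion to :func:`generate_cohort`: participant
    offsets are symmetric around zero within each group, and a +/- pattern
    orthogonal to the participant and cell effects provides a nonzero
    residual variance, so every group x time x region x layer sample mean
    equals the requested ``cell_means`` value to machine precision while
    the mixed model remains estimable.  Requires an even ``n_per_group``.
    """
    if n_per_group % 2:
        raise ValueError("n_per_group must be even for exact cell means")
    groups = sorted({g for (g, _, _, _) in cell_means})
    region_layers = sorted({(r, l) for (_, _, r, l) in cell_means})
    offsets = (
        np.linspace(-1.0, 1.0, n_per_group) * intercept_spread
        if n_per_group > 1
        else np.zeros(1)
    )
    rows = []
    for group in groups:
        for i in range(n_per_group):
            sgn = 1.0 if i % 2 == 0 else -1.0
            for time in TIMES:
                tsgn = 1.0 if time == "pre" else -1.0
                for region, layer in region_layers:
                    mu = cell_means[(group, time, region, layer)]
                    rows.append(
                        {
                            "participant_id": f"{group}-{i + 1:02d}",
                            "group": group,
                            "time": time,
                            "region": region,
                            "layer": layer,
                            "value": mu + offsets[i] + sgn * tsgn * residual_spread,
                            "age": np.nan,
                            "bmi": np.nan,
                        }
                    )
    return pd.DataFrame(rows)
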