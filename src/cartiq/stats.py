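"""Group x time mixed-effects analysis of regional cartilage measures.

The measurement unit is a long-format table with one row per
participant x time x region x layer.  For each response cell
(region, layer) the model is a linear mixed model

    y_ijt = beta_0 + beta_g * group + beta_t * time + beta_gt * group x time
            (+ covariates) + b_i + eps_ijt,

with a random intercept b_i per participant, fitted by REML.  Reported
quantities are the adjusted cell means per group x time (at covariate
means when covariates are included), the within-group pre-to-post
changes, and all pairwise between-group differences of changes, each
with a normal-approximation 95% CI, a raw two-sided p-value and a
Sidak-adjusted p-value.  In the two-group case the between-group
difference of changes equals the interaction coefficient identically.

The family for the Sidak adjustment defaults to the set of reported
pairwise comparisons — the G within-group changes plus the C(G,2)
between-group differences (m = 3 for two groups) — and is configurable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm

from .images import LAMINA_DEEP, LAMINA_SUPERFICIAL, LaminarMask, T2Map, same_grid

LAYER_NAMES = {LAMINA_SUPERFICIAL: "superficial", LAMINA_DEEP: "deep"}
COMPOSITE_REGION = "composite"


# ---------------------------------------------------------------------------
# aggregation: voxels -> table rows
# ---------------------------------------------------------------------------

def region_layer_means(
    t2map: T2Map,
    laminae: LaminarMask,
    slices: range | None = None,
    region_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Mean of valid voxels per region x lamina over a slice range.

    Rows with zero valid voxels are emitted with a NaN value and a zero
    count rather than dropped, so missingness stays visible downstream.
    """
    if t2map.t2.shape != laminae.codes.shape or not same_grid(t2map.grid, laminae.grid):
        raise ValueError("map and laminar mask are on different grids")
    sel = np.zeros(t2map.t2.shape, dtype=bool)
    sel[list(slices) if slices is not None else slice(None)] = True

    rows = []
    for region in sorted(int(r) for r in np.unique(laminae.regions) if r >= 2):
        for code, layer in LAYER_NAMES.items():
            cell = laminae.lamina_mask(region, code) & sel & t2map.valid
            n = int(cell.sum())
            value = float(np.mean(t2map.t2[cell])) if n else np.nan
            name = (region_names or {}).get(region, str(region))
            rows.append(
                {"region": name, "layer": layer, "value": value, "n_voxels": n}
            )
    return pd.DataFrame(rows)


def composite(
    table: pd.DataFrame, regions: list[str] | None = None, layer: str = "superficial"
) -> pd.DataFrame:
    """Composite measure: unweighted mean of the regional means per
    participant x time for one layer.

    Every region in ``regions`` (default: all regions in the table other
    than the composite itself) must be present and non-missing for a
    participant x time; otherwise that composite cell is NaN.
    """
    sub = table[table["layer"] == layer]
    if regions is None:
        regions = sorted(r for r in sub["region"].unique() if r != COMPOSITE_REGION)
    sub = sub[sub["region"].isin(regions)]

    keys = ["participant_id", "group", "time"]
    extra = [c for c in ("age", "bmi") if c in table.columns]
    rows = []
    for key, cell in sub.groupby(keys, sort=True):
        have = set(cell["region"])
        complete = set(regions) <= have and not cell["value"].isna().any()
        value = float(cell["value"].mean()) if complete else np.nan
        rec = dict(zip(keys, key))
        rec.update({"region": COMPOSITE_REGION, "layer": layer, "value": value})
        for c in extra:
            rec[c] = cell[c].iloc[0]
        rows.append(rec)
    return pd.DataFrame(rows)


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak multiplicity adjustment ``1 - (1 - p)^m``, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1 or int(m) != m:
        raise ValueError("family size m must be a positive integer")
    # clamp to [p, 1]: the adjusted p can never fall below the raw p,
    # which the naive power form can violate by one ulp at m = 1
    out = np.minimum(1.0, np.maximum(p, 1.0 - (1.0 - p) ** m))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class GroupTimeResults:
    """Fitted group x time mixed model for one response cell.

    ``cell_means`` holds the adjusted mean per group x time with 95% CI;
    ``contrasts`` the within-group changes and pairwise between-group
    differences of changes with SEs, CIs, raw and Sidak-adjusted
    p-values.  ``degenerate`` marks fits on data with (numerically) zero
    residual variance: point estimates are exact but SEs, CIs and
    p-values are undefined and reported as NaN.
    """

    region: str
    layer: str
    groups: list[str]
    params: pd.Series
    cov_params: pd.DataFrame
    sigma_b2: float
    sigma_e2: float
    cell_means: pd.DataFrame
    contrasts: pd.DataFrame
    m_sidak: int
    n_obs: int
    n_participants: int
    converged: bool
    degenerate: bool
    covariates: list[str] = field(default_factory=list)

    @property
    def interaction(self) -> float:
        """The group x time interaction coefficient (first non-reference
        group), identical to its between-group difference of changes."""
        key = [k for k in self.params.index if ":" in k]
        return float(self.params[key[0]]) if key else np.nan

    def within_change(self, group: str) -> float:
        row = self.contrasts[self.contrasts["contrast"] == f"within:{group}"]
        return float(row["estimate"].iloc[0])

    def between_difference(self, group_a: str, group_b: str) -> float:
        """Difference of changes, group_a change minus group_b change."""
        name = f"between:{group_a}-{group_b}"
        row = self.contrasts[self.contrasts["contrast"] == name]
        if row.empty:
            row = self.contrasts[self.contrasts["contrast"] == f"between:{group_b}-{group_a}"]
            return -float(row["estimate"].iloc[0])
        return float(row["estimate"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Group x time mixed model — region {self.region!r}, layer {self.layer!r}",
            f"  observations: {self.n_obs}  participants: {self.n_participants}"
            f"  groups: {', '.join(self.groups)}",
            f"  REML variance components: sigma_b^2 = {self.sigma_b2:.4g}, "
            f"sigma_e^2 = {self.sigma_e2:.4g}"
            + ("  [degenerate: zero residual variance]" if self.degenerate else ""),
            "",
            "  Adjusted cell means (95% CI):",
        ]
        for _, r in self.cell_means.iterrows():
            lines.append(
                f"    {r['group']:>12} {r['time']:>5}: {r['mean']:8.3f} "
                f"({r['ci_low']:.3f}; {r['ci_high']:.3f})"
            )
        lines += ["", f"  Contrasts (Sidak family m = {self.m_sidak}):"]
        for _, r in self.contrasts.iterrows():
            lines.append(
                f"    {r['contrast']:>28}: {r['estimate']:8.3f} "
                f"({r['ci_low']:.3f}; {r['ci_high']:.3f})  "
                f"p = {r['p_raw']:.4g}  p_sidak = {r['p_sidak']:.4g}"
            )
        return "\n".join(lines)

    def plot_cells(self, ax=None):
        """Pre/post adjusted means per group with CI whiskers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, g in enumerate(self.groups):
            sub = self.cell_means[self.cell_means["group"] == g]
            sub = sub.set_index("time").loc[["pre", "post"]]
            x = np.arange(2) + 0.05 * i
            ax.errorbar(
                x,
                sub["mean"],
                yerr=[sub["mean"] - sub["ci_low"], sub["ci_high"] - sub["mean"]],
                marker="o",
                capsize=3,
                label=g,
            )
        ax.set_xticks([0, 1], ["pre", "post"])
        ax.set_ylabel(f"{self.region} / {self.layer}")
        ax.legend()
        return ax


class GroupTimeModel:
    """Linear mixed model for one region x layer response cell.

    Parameters
    ----------
    table : DataFrame
        Long-format measurements with columns participant_id, group,
        time, region, layer, value (and optional covariates).
    region, layer : str
        The response cell to model; rows outside it are ignored.
    covariates : sequence of str
        Optional per-participant covariate columns (e.g. age, bmi),
        centred internally so that adjusted means refer to the sample
        covariate mean.
    groups_order : sequence of str, optional
        Reference group first; defaults to sorted labels with "healthy"
        promoted to the front when present.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        region: str,
        layer: str,
        covariates: tuple[str, ...] = (),
        groups_order: list[str] | None = None,
    ) -> None:
        sub = table[(table["region"] == region) & (table["layer"] == layer)].copy()
        sub = sub.dropna(subset=["value"])
        if sub.empty:
            raise ValueError(f"no rows for response cell ({region}, {layer})")
        for cov in covariates:
            if cov not in sub.columns:
                raise ValueError(f"covariate column {cov!r} missing from table")
            sub = sub.dropna(subset=[cov])

        groups = sorted(sub["group"].unique())
        if groups_order is not None:
            if set(groups_order) != set(groups):
                raise ValueError("groups_order must list exactly the observed groups")
            groups = list(groups_order)
        elif "healthy" in groups:
            groups = ["healthy"] + [g for g in groups if g != "healthy"]
        if len(groups) < 2:
            raise ValueError("at least two groups are required")
        for g in groups:
            gg = sub[sub["group"] == g]
            if gg["participant_id"].nunique() < 2:
                raise ValueError(f"group {g!r} has fewer than two participants")
            if set(gg["time"]) != {"pre", "post"}:
                raise ValueError(f"group {g!r} is not observed at both timepoints")

        self.table = sub
        self.region = region
        self.layer = layer
        self.groups = groups
        self.covariates = list(covariates)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "GroupTimeModel":
        return cls(table, **kwargs)

    # -- design ------------------------------------------------------------

    def _design(self) -> tuple[np.ndarray, list[str], pd.DataFrame]:
        sub = self.table
        names = ["intercept"]
        cols = [np.ones(len(sub))]
        post = (sub["time"] == "post").to_numpy(float)
        for g in self.groups[1:]:
            cols.append((sub["group"] == g).to_numpy(float))
            names.append(f"group[{g}]")
        cols.append(post)
        names.append("time[post]")
        for g in self.groups[1:]:
            cols.append((sub["group"] == g).to_numpy(float) * post)
            names.append(f"group[{g}]:time[post]")
        for cov in self.covariates:
            x = sub[cov].to_numpy(float)
            cols.append(x - x.mean())
            names.append(cov)
        return np.column_stack(cols), names, sub

    def _cell_vector(self, names: list[str], group: str, time: str) -> np.ndarray:
        """Design row of a group x time cell at centred-covariate zero."""
        v = np.zeros(len(names))
        v[names.index("intercept")] = 1.0
        if group != self.groups[0]:
            v[names.index(f"group[{group}]")] = 1.0
        if time == "post":
            v[names.index("time[post]")] = 1.0
            if group != self.groups[0]:
                v[names.index(f"group[{group}]:time[post]")] = 1.0
        return v

    # -- estimation --------------------------------------------------------

    def fit(self, reml: bool = True, m_sidak: int | None = None) -> GroupTimeResults:
        """Fit by (RE)ML and assemble cell means and contrasts.

        Raises on a singular design; a fit whose variance estimation does
        not converge raises with diagnostics unless the data are exactly
        degenerate (zero residual variance), in which case exact point
        estimates are returned with NaN uncertainties.
        """
        X, names, sub = self._design()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design: a group or timepoint is unobserved")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(sub["value"].to_numpy(), X, groups=sub["participant_id"])
            try:
                res = model.fit(reml=reml)
            except Exception as exc:  # singular covariance etc.
                raise RuntimeError(f"mixed-model estimation failed: {exc}") from exc

        params = pd.Series(np.asarray(res.fe_params), index=names)
        sigma_e2 = float(res.scale)
        sigma_b2 = float(np.asarray(res.cov_re)[0, 0])
        cov = np.asarray(res.cov_params())[: len(names), : len(names)]
        # residual variance indistinguishable from zero at the data's scale
        # (noiseless input): point estimates are exact, uncertainties are not
        # defined, and the optimizer cannot be expected to report convergence
        y_var = float(np.var(sub["value"].to_numpy()))
        degenerate = (
            not np.all(np.isfinite(cov))
            or sigma_e2 <= 1e-10 * max(y_var, 1.0)
        )
        if degenerate:
            cov = np.full((len(names), len(names)), np.nan)
        elif not res.converged:
            raise RuntimeError(
                "mixed-model variance estimation did not converge "
                f"(sigma_b^2={sigma_b2:.3g}, sigma_e^2={sigma_e2:.3g})"
            )
        cov_df = pd.DataFrame(cov, index=names, columns=names)

        z = sps.norm.ppf(0.975)

        def infer(vec: np.ndarray) -> tuple[float, float, float, float, float]:
            est = float(vec @ params.to_numpy())
            q = float(vec @ cov @ vec) if np.all(np.isfinite(cov)) else np.nan
            se = float(np.sqrt(q)) if q > 0 else np.nan
            if np.isfinite(se) and se > 0:
                p = 2.0 * sps.norm.sf(abs(est) / se)
            else:
                p = np.nan
            return est, se, est - z * se, est + z * se, p

        cells = []
        for g in self.groups:
            for t in ("pre", "post"):
                est, se, lo, hi, _ = infer(self._cell_vector(names, g, t))
                cells.append(
                    {"group": g, "time": t, "mean": est, "se": se, "ci_low": lo, "ci_high": hi}
                )
        cell_means = pd.DataFrame(cells)

        contrast_vecs: list[tuple[str, np.ndarray]] = []
        for g in self.groups:
            vec = self._cell_vector(names, g, "post") - self._cell_vector(names, g, "pre")
            contrast_vecs.append((f"within:{g}", vec))
        for ga, gb in itertools.combinations(self.groups[::-1], 2):
            # report "non-reference minus reference" first, e.g. at-risk - healthy
            vec = (
                self._cell_vector(names, ga, "post")
                - self._cell_vector(names, ga, "pre")
                - self._cell_vector(names, gb, "post")
                + self._cell_vector(names, gb, "pre")
            )
            contrast_vecs.append((f"between:{ga}-{gb}", vec))

        m = m_sidak if m_sidak is not None else len(contrast_vecs)
        rows = []
        for name, vec in contrast_vecs:
            est, se, lo, hi, p = infer(vec)
            rows.append(
                {
                    "contrast": name,
                    "estimate": est,
                    "se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_raw": p,
                    "p_sidak": sidak_adjust(p, m) if np.isfinite(p) else np.nan,
                }
            )
        contrasts = pd.DataFrame(rows)

        return GroupTimeResults(
            region=self.region,
            layer=self.layer,
            groups=self.groups,
            params=params,
            cov_params=cov_df,
            sigma_b2=sigma_b2,
            sigma_e2=sigma_e2,
            cell_means=cell_means,
            contrasts=contrasts,
            m_sidak=m,
            n_obs=len(sub),
            n_participants=sub["participant_id"].nunique(),
            converged=bool(res.converged) or degenerate,
            degenerate=degenerate,
            covariates=self.covariates,
        )


def fit_group_time_model(
    table: pd.DataFrame,
    region: str,
    layer: str,
    covariates: tuple[str, ...] = (),
    m_sidak: int | None = None,
    groups_order: list[str] | None = None,
) -> GroupTimeResults:
    """Convenience wrapper: build and fit a :class:`GroupTimeModel`."""
    model = GroupTimeModel(
        table, region, layer, covariates=covariates, groups_order=groups_order
    )
    return model.fit(m_sidak=m_sidak)


def contrasts(fit: GroupTimeResults) -> pd.DataFrame:
    """The contrast table of a fitted model (within-group changes and
    pairwise between-group differences of changes)."""
    return fit.contrasts.copy()
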