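"""Breed-level analysis with depth-of-coverage adjustment.

The number of variants detected per genome rises with sequencing depth of
coverage (DOC), so raw per-breed means confound breed and depth.  Breed
comparisons here fit an ordinary least-squares model

    count ~ C(breed) + doc

and report estimated marginal means (EMMEANs): the model prediction for
each breed at a common reference DOC (the grand mean over included
samples by default), with standard errors from the coefficient covariance
and 95% confidence intervals on the t(residual df) distribution.

Ne correlations pair every horse with its breed's published effective
population size estimate (n = horses, not breeds); confidence intervals
for Pearson's r use the Fisher z-transform.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf

OTHER_LABEL = "Other"

RESPONSES = ("n_variants", "n_burden", "n_burden_hom", "n_lof", "n_lof_hom")


def select_target_breeds(
    metadata: pd.DataFrame,
    min_n: int = 17,
    min_mean_doc: float = 5.0,
) -> tuple[list[str], pd.DataFrame]:
    """Choose target breeds; pool everything else as "Other".

    A breed qualifies with at least ``min_n`` samples and a breed-mean DOC
    strictly above ``min_mean_doc``.  Returns the sorted target list and a
    copy of the metadata with a ``breed_group`` column (target breed name,
    or "Other").  The "Other" label itself is always pooled.
    """
    if metadata.empty:
        raise ValueError("metadata is empty")
    stats = metadata.groupby("breed")["doc"].agg(["size", "mean"])
    targets = sorted(
        b
        for b, row in stats.iterrows()
        if b != OTHER_LABEL and row["size"] >= min_n and row["mean"] > min_mean_doc
    )
    if not targets:
        warnings.warn("no breed meets the inclusion criteria; all samples pooled as Other")
    out = metadata.copy()
    out["breed_group"] = np.where(out["breed"].isin(targets), out["breed"], OTHER_LABEL)
    return targets, out


@dataclasses.dataclass
class ModelFit:
    """An OLS fit of count ~ breed (+ DOC) with its provenance."""

    response: str
    result: object  # statsmodels RegressionResults
    breeds: tuple[str, ...]
    reference_breed: str
    doc_used: bool
    data: pd.DataFrame

    @property
    def doc_slope_p(self) -> float | None:
        return float(self.result.pvalues["doc"]) if self.doc_used else None

    @property
    def doc_slope(self) -> float | None:
        return float(self.result.params["doc"]) if self.doc_used else None

    @property
    def residual_df(self) -> float:
        return float(self.result.df_resid)

    @property
    def r_squared(self) -> float:
        return float(self.result.rsquared)


def _diagnose_singular(exog: np.ndarray, names: list[str]) -> str:
    """Name the design column(s) that are linearly dependent."""
    full_rank = np.linalg.matrix_rank(exog)
    dependent = []
    for j, name in enumerate(names):
        reduced = np.delete(exog, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            dependent.append(name)
    return ", ".join(dependent) or "unknown"


def fit_count_model(responses: pd.DataFrame, response: str = "count") -> ModelFit:
    """OLS fit of a per-sample count on breed (treatment coded) and DOC.

    ``responses`` needs columns ``breed_group``, ``doc`` and the response.
    The reference breed is the alphabetically first level.  A DOC column
    with no variation is dropped with a warning (the adjustment is then a
    no-op).  A singular design raises, naming the offending breed column.
    """
    df = responses.copy()
    levels = sorted(df["breed_group"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two breed levels to fit the count model")
    reference = levels[0]
    doc_used = float(df["doc"].std()) > 0
    if not doc_used:
        warnings.warn("DOC has no variation; fitting breed-only model")
    rhs = f"C(breed_group, Treatment(reference={reference!r}))"
    formula = f"{response} ~ {rhs} + doc" if doc_used else f"{response} ~ {rhs}"
    model = smf.ols(formula, data=df)
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        culprit = _diagnose_singular(exog, list(model.exog_names))
        raise ValueError(f"singular design matrix; dependent column(s): {culprit}")
    result = model.fit()
    return ModelFit(
        response=response,
        result=result,
        breeds=tuple(levels),
        reference_breed=reference,
        doc_used=doc_used,
        data=df,
    )


def estimate_emmeans(fit: ModelFit, at_doc: float | None = None) -> pd.DataFrame:
    """Per-breed estimated marginal means at a common DOC.

    Defaults to the grand-mean DOC over the fitted samples.  SE comes from
    the variance of the linear predictor under the coefficient covariance;
    the 95% CI uses the t distribution with the fit's residual df.
    """
    if at_doc is None:
        at_doc = float(fit.data["doc"].mean())
    grid = pd.DataFrame({"breed_group": list(fit.breeds), "doc": at_doc})
    pred = fit.result.get_prediction(grid)
    frame = pred.summary_frame(alpha=0.05)
    return pd.DataFrame(
        {
            "breed": list(fit.breeds),
            "response": fit.response,
            "emmean": frame["mean"].to_numpy(),
            "se": frame["mean_se"].to_numpy(),
            "ci_low": frame["mean_ci_lower"].to_numpy(),
            "ci_high": frame["mean_ci_upper"].to_numpy(),
            "at_doc": at_doc,
        }
    )


def breed_emmeans(
    sample_burden: pd.DataFrame,
    metadata: pd.DataFrame,
    responses: tuple[str, ...] = RESPONSES,
    min_n: int = 17,
    min_mean_doc: float = 5.0,
    at_doc: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Full breed analysis: select targets, fit, and tabulate EMMEANs.

    Returns the stacked EMMEAN table (one block per response, sorted by
    EMMEAN within block) and the target breed list.
    """
    targets, meta = select_target_breeds(metadata, min_n=min_n, min_mean_doc=min_mean_doc)
    df = sample_burden.merge(
        meta[["breed_group", "doc"]], left_on="sample_id", right_index=True
    )
    tables = []
    for resp in responses:
        if resp not in df.columns:
            continue
        fit = fit_count_model(df.rename(columns={resp: "count"}), response="count")
        em = estimate_emmeans(fit, at_doc=at_doc)
        em["response"] = resp
        tables.append(em.sort_values("emmean", kind="stable"))
    return pd.concat(tables, ignore_index=True), targets


def read_ne_table(path) -> pd.DataFrame:
    """Read the breed Ne table (columns ``breed``, ``ne``, ``source``)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"breed", "ne", "source"} - set(df.columns)
    if missing:
        raise ValueError(f"Ne table is missing columns: {sorted(missing)}")
    if (df["ne"] <= 0).any():
        raise ValueError("Ne estimates must be positive")
    if df.duplicated(["breed", "source"]).any():
        raise ValueError("duplicate (breed, source) rows in Ne table")
    return df


def correlate_burden_ne(
    sample_burden: pd.DataFrame,
    metadata: pd.DataFrame,
    ne_table: pd.DataFrame,
    responses: tuple[str, ...] = ("n_burden", "n_burden_hom", "n_lof", "n_lof_hom"),
) -> pd.DataFrame:
    """Pearson correlation of per-horse burden with breed-level Ne.

    Horses of breeds without an Ne estimate for a given source are
    excluded (and counted).  95% CIs use the Fisher z-transform.
    """
    df = sample_burden.merge(
        metadata[["breed"]], left_on="sample_id", right_index=True
    )
    rows = []
    for source, ne_src in ne_table.groupby("source"):
        merged = df.merge(ne_src[["breed", "ne"]], on="breed", how="left")
        excluded = int(merged["ne"].isna().sum())
        paired = merged.dropna(subset=["ne"])
        for resp in responses:
            if resp not in paired.columns:
                continue
            x = paired["ne"].to_numpy(float)
            y = paired[resp].to_numpy(float)
            if len(x) < 3:
                raise ValueError(f"fewer than 3 paired observations for {resp} vs {source}")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(
                    f"correlation undefined for {resp} vs {source}: constant input"
                )
            res = sps.pearsonr(x, y)
            ci = res.confidence_interval(confidence_level=0.95)
            rows.append(
                {
                    "response": resp,
                    "source": source,
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                    "ci_low": float(ci.low),
                    "ci_high": float(ci.high),
                    "n": len(x),
                    "n_excluded": excluded,
                }
            )
    return pd.DataFrame(rows)


def compare_frequencies(freqs_burden: np.ndarray, freqs_other: np.ndarray) -> dict:
    """Welch two-sample t comparison of per-variant frequencies.

    Reports the mean difference (burden minus other) with a 95% CI and
    the medians/IQRs of both groups.
    """
    a = np.asarray(freqs_burden, dtype=float)
    b = np.asarray(freqs_other, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence_level=0.95)

    def _miqr(x):
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3)}

    return {
        "mean_difference": float(a.mean() - b.mean()),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "group_burden": _miqr(a),
        "group_other": _miqr(b),
        "n_burden": len(a),
        "n_other": len(b),
    }
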