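"""Interpretation of MDS dimensions by regression on word norms.

Each latent dimension is regressed (OLS with intercept) on the eight word
norms — concreteness, valence, arousal, dominance, age of acquisition,
orthographic neighbourhood density, length and prevalence.  Predictors are
z-scored within the word set by default so coefficient magnitudes are
comparable across fits; coordinates stay in sampled units.  Significance is
two-tailed at |t| > 1.96, uncorrected.  Repeating the regression over the 50
aligned posterior samples turns sampling uncertainty in the configuration
into a distribution of t-values per predictor and dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bmds import BmdsConfig, PosteriorSamples, align_samples, fit_bmds
from .stimuli import PREDICTOR_FEATURES, WordSet

T_CRITICAL = 1.96


@dataclass
class RegressionResult:
    """Per-dimension OLS summary: one row per predictor."""

    dimension: int
    table: pd.DataFrame        # index predictor; columns beta, se, t, p
    n_words: int

    def significant(self, t_crit: float = T_CRITICAL) -> list[str]:
        return list(self.table.index[self.table["t"].abs() > t_crit])


@dataclass
class SampleRegressionDistribution:
    """t-value distributions over posterior samples."""

    dimension: int
    t_values: pd.DataFrame     # rows = samples, columns = predictors

    @property
    def frac_significant(self) -> pd.Series:
        return (self.t_values.abs() > T_CRITICAL).mean(axis=0)

    def majority_significant(self) -> list[str]:
        fs = self.frac_significant
        return list(fs.index[fs > 0.5])


def _design_matrix(ws: WordSet, standardize: bool) -> pd.DataFrame:
    if standardize:
        return ws.zscored_features()
    X = ws.feature_matrix()
    return pd.DataFrame(X, columns=list(PREDICTOR_FEATURES), index=ws.word_ids)


def regress_dimension(
    coords_dim: np.ndarray,
    ws: WordSet,
    dimension: int = 1,
    standardize: bool = True,
) -> RegressionResult:
    """OLS of one dimension's per-word coordinates on the eight norms."""
    y = np.asarray(coords_dim, dtype=float)
    n = len(ws)
    if len(y) != n:
        raise ValueError("coords_dim length must match the word set")
    if n < 10:
        raise ValueError("need at least 10 words for an interpretable fit")
    Xdf = _design_matrix(ws, standardize)
    rank = np.linalg.matrix_rank(Xdf.to_numpy())
    if rank < Xdf.shape[1]:
        corr = np.corrcoef(Xdf.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "predictor matrix is rank deficient; most collinear columns: "
            f"{Xdf.columns[i]!r} and {Xdf.columns[j]!r}"
        )
    X = sm.add_constant(Xdf)
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).drop(index="const")
    return RegressionResult(dimension=dimension, table=table, n_words=n)


def regress_posterior_samples(
    ps: PosteriorSamples, ws: WordSet, standardize: bool = True
) -> dict[int, SampleRegressionDistribution]:
    """Per-sample regressions for both dimensions of an aligned posterior.

    Refuses unaligned samples: without a common frame the per-sample
    coordinate axes are arbitrary rotations of each other and the t-value
    distribution would mix incomparable quantities.
    """
    if not ps.aligned:
        raise ValueError("posterior samples must be aligned before regression")
    if list(ps.word_ids) != list(ws.word_ids):
        raise ValueError("posterior word_ids do not match the word set")
    out = {}
    for dim in (1, 2):
        ts = []
        for s in range(ps.n_samples):
            res = regress_dimension(
                ps.samples[s, :, dim - 1], ws, dimension=dim,
                standardize=standardize,
            )
            ts.append(res.table["t"])
        out[dim] = SampleRegressionDistribution(
            dimension=dim, t_values=pd.DataFrame(ts).reset_index(drop=True)
        )
    return out


def interpret_fit(
    ps: PosteriorSamples, ws: WordSet, standardize: bool = True
) -> tuple[dict[int, RegressionResult], dict[int, SampleRegressionDistribution]]:
    """Posterior-mean and per-sample regressions for an aligned fit."""
    mean_cfg = ps.posterior_mean
    mean_res = {
        dim: regress_dimension(mean_cfg[:, dim - 1], ws, dim, standardize)
        for dim in (1, 2)
    }
    return mean_res, regress_posterior_samples(ps, ws, standardize)


def interpret_patient(
    responses: pd.DataFrame,
    ws: WordSet,
    config: BmdsConfig | None = None,
    seed: int = 0,
    reference: np.ndarray | None = None,
    standardize: bool = True,
):
    """Single-participant fit plus dimension regressions.

    ``responses`` must contain one participant's triad rows.  An optional
    ``reference`` configuration (e.g. a pooled control fit's posterior mean)
    fixes the orientation of the patient's space before regression.
    """
    pids = responses["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected one participant, got {len(pids)}")
    ps = fit_bmds(responses, ws.word_ids, config, seed=seed)
    if reference is not None:
        ps = align_samples(ps, reference=reference)
    return interpret_fit(ps, ws, standardize)


def report_frame(
    label: str,
    mean_results: dict[int, RegressionResult],
    sample_dists: dict[int, SampleRegressionDistribution] | None = None,
) -> pd.DataFrame:
    """Flat report: group_or_patient, dimension, predictor, beta, se, t, p,
    frac_samples_significant."""
    rows = []
    for dim, res in mean_results.items():
        frac = (
            sample_dists[dim].frac_significant if sample_dists else None
        )
        for pred, row in res.table.iterrows():
            rows.append(
                {
                    "group_or_patient": label,
                    "dimension": dim,
                    "predictor": pred,
                    "beta": row["beta"],
                    "se": row["se"],
                    "t": row["t"],
                    "p": row["p"],
                    "frac_samples_significant":
                        float(frac[pred]) if frac is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
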