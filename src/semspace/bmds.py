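"""Bayesian multidimensional scaling of odd-one-out triad judgements.

Model
-----
Each word lives at an unknown 2D coordinate with a uniform prior on the unit
square.  On a triad (A, B, C) a participant designates word X as the odd one
out with probability proportional to ``exp(-delta_p * d(Y, Z))`` where
(Y, Z) are the other two words, ``d`` is the Minkowski-r distance, and
``delta_p > 0`` is the participant's response determinism (Gamma prior).
Small pairwise distances make the third word a likely odd-one-out, so the
posterior over coordinates concentrates on configurations whose distance
structure explains the choices.  Inference is random-walk Metropolis within
Gibbs: per-word coordinate blocks and per-participant delta updates, with
step sizes adapted during warmup only.  The likelihood is invariant to
rotation, reflection and translation, so retained samples are Procrustes-
aligned (rigid, no scaling) before any coordinate-level summary, and
convergence is diagnosed on pairwise distances, which are identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import minkowski_distance


@dataclass
class BmdsConfig:
    """Sampler and model settings.

    Parameters
    ----------
    n_dims
        Latent dimensionality; only 2 is supported (the analysis is defined
        for planar configurations).
    minkowski_r
        Distance exponent, >= 1; 2 (Euclidean) by default.
    support
        (low, high) bounds of the uniform coordinate prior per axis.
    delta_shape, delta_rate
        Gamma prior on each participant's determinism delta.
    warmup, kept
        Number of adaptation sweeps discarded, and post-warmup sweeps from
        which retained draws are thinned.
    n_retain
        Number of approximately equally spaced posterior draws kept (50 by
        convention: enough to propagate posterior uncertainty through the
        downstream regressions and randomness statistics).
    init
        "mds" (classical scaling of an empirical dissimilarity built from
        the responses) or "random".
    rhat_threshold
        Split-chain convergence threshold on pairwise-distance traces; a
        value above it is recorded as a warning in the diagnostics, not an
        error.
    """

    n_dims: int = 2
    minkowski_r: float = 2.0
    support: tuple[float, float] = (0.0, 1.0)
    delta_shape: float = 2.0
    delta_rate: float = 1.0
    warmup: int = 2000
    kept: int = 5000
    n_retain: int = 50
    init: str = "mds"
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_dims != 2:
            raise ValueError("only 2 latent dimensions are supported")
        if self.minkowski_r < 1:
            raise ValueError("minkowski_r must be >= 1")
        if self.kept < self.n_retain:
            raise ValueError("kept sweeps must be >= n_retain")


def reduced_config(**overrides) -> BmdsConfig:
    """A test-scale configuration (shorter chains, same model)."""
    defaults = dict(warmup=400, kept=1000)
    defaults.update(overrides)
    return BmdsConfig(**defaults)


@dataclass
class PosteriorSamples:
    """Retained, optionally aligned, posterior draws of a BMDS fit."""

    samples: np.ndarray            # (n_retain, n_words, 2)
    deltas: np.ndarray             # (n_retain, n_participants)
    word_ids: list[str]
    participant_ids: list[str]
    aligned: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def posterior_mean(self) -> np.ndarray:
        """Mean configuration over aligned samples (requires alignment)."""
        if not self.aligned:
            raise ValueError(
                "posterior mean of unaligned samples is meaningless; call "
                "align_samples first"
            )
        return self.samples.mean(axis=0)

    def mean_distance_matrix(self, r: float = 2.0) -> np.ndarray:
        """Posterior mean of the pairwise distance matrix (alignment-free)."""
        n = len(self.word_ids)
        out = np.zeros((n, n))
        for s in self.samples:
            diff = np.abs(s[:, None, :] - s[None, :, :])
            out += np.sum(diff ** r, axis=-1) ** (1.0 / r)
        return out / self.n_samples


# --------------------------------------------------------------------------
# Likelihood
# --------------------------------------------------------------------------

def triad_choice_prob(
    coords: np.ndarray, triad, delta: float, r: float = 2.0
) -> np.ndarray:
    """Probability triple that word A, B, C of the triad is the odd one out."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    a, b, c = triad
    if len({a, b, c}) != 3:
        raise ValueError("triad must contain three distinct words")
    d = np.array(
        [
            minkowski_distance(coords[b], coords[c], r),
            minkowski_distance(coords[a], coords[c], r),
            minkowski_distance(coords[a], coords[b], r),
        ]
    )
    logits = -delta * d
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def _subset_logliks(X, tri, obs, delta_t, r):
    """Log-likelihood of the observed odd words for a subset of trials."""
    if len(obs) == 0:
        return np.zeros(0)
    d0 = minkowski_distance(X[tri[:, 1]], X[tri[:, 2]], r)
    d1 = minkowski_distance(X[tri[:, 0]], X[tri[:, 2]], r)
    d2 = minkowski_distance(X[tri[:, 0]], X[tri[:, 1]], r)
    logits = -delta_t[:, None] * np.stack([d0, d1, d2], axis=1)
    m = logits.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
    return logits[np.arange(len(obs)), obs] - lse


def _prepare(responses: pd.DataFrame, word_ids: list[str]):
    """Index the long triad-response table into sampler arrays."""
    required = {"participant_id", "word1", "word2", "word3", "choice"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"triad responses missing columns: {sorted(missing)}")
    widx = {w: i for i, w in enumerate(word_ids)}
    participants = sorted(responses["participant_id"].astype(str).unique())
    pidx = {p: i for i, p in enumerate(participants)}

    tri = np.empty((len(responses), 3), dtype=np.int64)
    obs = np.empty(len(responses), dtype=np.int64)
    part = np.empty(len(responses), dtype=np.int64)
    for k, row in enumerate(responses.itertuples()):
        words = (str(row.word1), str(row.word2), str(row.word3))
        try:
            tri[k] = [widx[w] for w in words]
        except KeyError as e:
            raise ValueError(f"response references unknown word {e.args[0]!r}")
        choice = str(row.choice)
        if choice not in words:
            raise ValueError(
                f"choice {choice!r} not among trial words {words}"
            )
        obs[k] = words.index(choice)
        part[k] = pidx[str(row.participant_id)]
    return tri, obs, part, participants


def log_posterior(
    coords: np.ndarray,
    deltas: np.ndarray,
    responses: pd.DataFrame,
    word_ids: list[str],
    config: BmdsConfig | None = None,
) -> float:
    """Unnormalized log posterior of a coordinate/delta state.

    The likelihood sums the log choice probability of every observed odd
    word; the prior is uniform on the support square (−inf outside) plus
    independent Gamma densities on the deltas.
    """
    config = config or BmdsConfig()
    coords = np.asarray(coords, dtype=float)
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    lo, hi = config.support
    if np.any(coords < lo) or np.any(coords > hi):
        return -np.inf
    if np.any(deltas <= 0):
        return -np.inf
    lp = float(
        stats.gamma.logpdf(
            deltas, a=config.delta_shape, scale=1.0 / config.delta_rate
        ).sum()
    )
    # uniform coordinate prior: constant density on the support
    lp += -coords.size * np.log(hi - lo)
    if len(responses) == 0:
        return lp
    tri, obs, part, _ = _prepare(responses, word_ids)
    if part.max() >= len(deltas):
        raise ValueError("fewer deltas than participants in the responses")
    ll = _subset_logliks(coords, tri, obs, deltas[part], config.minkowski_r)
    return lp + float(ll.sum())


# --------------------------------------------------------------------------
# Initialization
# --------------------------------------------------------------------------

def _classical_mds_init(tri, obs, n_words, rng, support):
    """Torgerson scaling of an empirical dissimilarity from odd-one-out counts.

    For each word pair, the fraction of co-occurring trials in which the pair
    was implicitly chosen as most similar (the third word odd) estimates
    similarity; 1 minus that is the dissimilarity seeded into classical MDS.
    """
    chosen = np.zeros((n_words, n_words))
    seen = np.zeros((n_words, n_words))
    pair_pos = [(1, 2), (0, 2), (0, 1)]
    for t in range(len(tri)):
        a, b, c = tri[t]
        for i, j in ((a, b), (a, c), (b, c)):
            seen[i, j] += 1
            seen[j, i] += 1
        i, j = tri[t][pair_pos[obs[t]][0]], tri[t][pair_pos[obs[t]][1]]
        chosen[i, j] += 1
        chosen[j, i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(seen > 0, chosen / np.maximum(seen, 1), np.nan)
    dis = 1.0 - sim
    fill = np.nanmean(dis) if np.isfinite(np.nanmean(dis)) else 0.5
    dis = np.where(np.isfinite(dis), dis, fill)
    np.fill_diagonal(dis, 0.0)
    dis = (dis + dis.T) / 2

    D2 = dis ** 2
    J = np.eye(n_words) - np.ones((n_words, n_words)) / n_words
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    vals2 = np.clip(vals[order], 0, None)
    X = vecs[:, order] * np.sqrt(vals2)
    X += rng.normal(0, 1e-3, X.shape)  # break exact degeneracies
    lo, hi = support
    span = X.max(axis=0) - X.min(axis=0)
    span = np.where(span == 0, 1.0, span)
    margin = 0.05 * (hi - lo)
    X = (X - X.min(axis=0)) / span * (hi - lo - 2 * margin) + lo + margin
    return X


# --------------------------------------------------------------------------
# Sampler
# --------------------------------------------------------------------------

def fit_bmds(
    responses: pd.DataFrame,
    word_ids: list[str],
    config: BmdsConfig | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Fit the BMDS model to one or many participants' triad responses.

    All participants in ``responses`` share the latent configuration (a
    pooled fit); each gets its own delta.  Pass a single participant's rows
    for an individual fit.  Deterministic given ``seed``.
    """
    config = config or BmdsConfig()
    if len(word_ids) < 2:
        raise ValueError("need at least two words")
    if len(responses) == 0:
        # prior recovery: no data, sample coordinates from the uniform prior
        tri = np.empty((0, 3), dtype=np.int64)
        obs = np.empty(0, dtype=np.int64)
        part = np.empty(0, dtype=np.int64)
        participants: list[str] = []
    else:
        tri, obs, part, participants = _prepare(responses, word_ids)
    n_words = len(word_ids)
    n_part = len(participants)
    rng = np.random.default_rng(seed)
    lo, hi = config.support
    r = config.minkowski_r

    if config.init == "mds" and len(obs) > 0:
        X = _classical_mds_init(tri, obs, n_words, rng, config.support)
    else:
        X = rng.uniform(lo, hi, size=(n_words, 2))
    deltas = np.full(n_part, config.delta_shape / config.delta_rate)

    trials_of_word = [np.where((tri == w).any(axis=1))[0] for w in range(n_words)]
    trials_of_part = [np.where(part == p)[0] for p in range(n_part)]

    cur_ll = _subset_logliks(X, tri, obs, deltas[part], r)

    step_x = np.full(n_words, 0.1 * (hi - lo))
    step_d = np.full(n_part, 0.3)
    acc_x = np.zeros(n_words)
    acc_d = np.zeros(n_part)
    prop_x = np.zeros(n_words)
    prop_d = np.zeros(n_part)

    n_sweeps = config.warmup + config.kept
    thin = max(1, config.kept // config.n_retain)
    retain_at = set(
        config.warmup + config.kept - 1 - thin * k for k in range(config.n_retain)
    )

    kept_X: list[np.ndarray] = []
    kept_d: list[np.ndarray] = []
    # dense distance traces (a pair subset) for split-chain diagnostics
    n_diag_pairs = min(20, n_words * (n_words - 1) // 2)
    iu = np.triu_indices(n_words, 1)
    diag_sel = rng.choice(len(iu[0]), size=n_diag_pairs, replace=False)
    diag_pairs = (iu[0][diag_sel], iu[1][diag_sel])
    diag_trace: list[np.ndarray] = []

    gshape, grate = config.delta_shape, config.delta_rate

    for sweep in range(n_sweeps):
        warm = sweep < config.warmup
        # --- per-word coordinate blocks
        for w in rng.permutation(n_words):
            sub = trials_of_word[w]
            prop = X[w] + rng.normal(0, step_x[w], size=2)
            prop_x[w] += 1
            if np.any(prop < lo) or np.any(prop > hi):
                continue
            X_old = X[w].copy()
            X[w] = prop
            new_ll = _subset_logliks(X, tri[sub], obs[sub], deltas[part[sub]], r)
            log_alpha = new_ll.sum() - cur_ll[sub].sum()
            if np.log(rng.random()) < log_alpha:
                cur_ll[sub] = new_ll
                acc_x[w] += 1
            else:
                X[w] = X_old
        # --- per-participant deltas (log-scale random walk)
        for p in range(n_part):
            sub = trials_of_part[p]
            d_old = deltas[p]
            d_new = d_old * np.exp(rng.normal(0, step_d[p]))
            prop_d[p] += 1
            deltas[p] = d_new
            new_ll = _subset_logliks(X, tri[sub], obs[sub], deltas[part[sub]], r)
            log_alpha = (
                new_ll.sum() - cur_ll[sub].sum()
                + (gshape * np.log(d_new) - grate * d_new)
                - (gshape * np.log(d_old) - grate * d_old)
            )  # Gamma prior plus log-proposal Jacobian folded into the shape term
            if np.log(rng.random()) < log_alpha:
                cur_ll[sub] = new_ll
                acc_d[p] += 1
            else:
                deltas[p] = d_old
        # --- warmup step-size adaptation
        if warm and (sweep + 1) % 50 == 0:
            with np.errstate(invalid="ignore"):
                rate_x = np.where(prop_x > 0, acc_x / np.maximum(prop_x, 1), 0.3)
                rate_d = np.where(prop_d > 0, acc_d / np.maximum(prop_d, 1), 0.3)
            step_x = np.clip(step_x * np.exp(rate_x - 0.3), 1e-4, hi - lo)
            step_d = np.clip(step_d * np.exp(rate_d - 0.3), 1e-3, 3.0)
            acc_x[:] = 0
            prop_x[:] = 0
            acc_d[:] = 0
            prop_d[:] = 0
        if not warm:
            diff = np.abs(X[diag_pairs[0]] - X[diag_pairs[1]])
            diag_trace.append(np.sum(diff ** r, axis=-1) ** (1.0 / r))
            if sweep in retain_at:
                kept_X.append(X.copy())
                kept_d.append(deltas.copy())

    samples = np.stack(kept_X)
    delta_draws = np.stack(kept_d)
    diagnostics = _diagnostics(
        np.stack(diag_trace), acc_x, prop_x, acc_d, prop_d, config
    )
    ps = PosteriorSamples(
        samples=samples,
        deltas=delta_draws,
        word_ids=list(word_ids),
        participant_ids=participants,
        aligned=False,
        diagnostics=diagnostics,
    )
    return align_samples(ps)


def _diagnostics(dist_trace, acc_x, prop_x, acc_d, prop_d, config) -> dict:
    import arviz as az

    n = dist_trace.shape[0] // 2 * 2
    rhats = []
    for j in range(dist_trace.shape[1]):
        tr = dist_trace[:n, j].reshape(2, n // 2)  # split-chain halves
        res = az.rhat(tr)
        val = float(res["x"].values) if hasattr(res, "data_vars") else float(res)
        rhats.append(val)
    max_rhat = float(np.nanmax(rhats)) if rhats else float("nan")
    diag = {
        "accept_rate_coords": float(np.sum(acc_x) / max(np.sum(prop_x), 1)),
        "accept_rate_delta": float(np.sum(acc_d) / max(np.sum(prop_d), 1)),
        "split_rhat_distances": rhats,
        "max_split_rhat": max_rhat,
        "converged": bool(max_rhat < config.rhat_threshold)
        if np.isfinite(max_rhat)
        else False,
    }
    if not diag["converged"]:
        diag["warning"] = (
            f"split-chain R-hat on pairwise distances reached {max_rhat:.3f} "
            f"(threshold {config.rhat_threshold}); consider longer chains"
        )
    return diag


# --------------------------------------------------------------------------
# Alignment
# --------------------------------------------------------------------------

def _rigid_align(sample: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Translation + rotation/reflection (no scaling) of sample onto reference."""
    mu_s = sample.mean(axis=0)
    mu_r = reference.mean(axis=0)
    A = sample - mu_s
    B = reference - mu_r
    U, _, Vt = np.linalg.svd(A.T @ B)
    R = U @ Vt
    return A @ R + mu_r


def align_samples(
    ps: PosteriorSamples, reference: np.ndarray | None = None, n_iter: int = 3
) -> PosteriorSamples:
    """Procrustes-align retained samples to a common frame.

    Rigid transforms only, so every sample's pairwise distances are exactly
    preserved.  Without an explicit ``reference`` the template is iterated:
    align to the first sample, then repeatedly to the current mean.  Pass the
    generating (ground-truth) configuration as ``reference`` when comparing a
    fit against a known simulated space — the likelihood cannot identify the
    orientation, so only an external reference makes axes comparable.
    """
    if ps.n_samples < 1:
        raise ValueError("need at least one sample")
    samples = ps.samples.copy()
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        aligned = np.stack([_rigid_align(s, ref) for s in samples])
    else:
        ref = samples[0]
        for _ in range(n_iter):
            aligned = np.stack([_rigid_align(s, ref) for s in samples])
            ref = aligned.mean(axis=0)
    return replace(ps, samples=aligned, aligned=True)


# --------------------------------------------------------------------------
# Posterior I/O
# --------------------------------------------------------------------------

def samples_to_frame(ps: PosteriorSamples) -> pd.DataFrame:
    rows = []
    for s in range(ps.n_samples):
        for w, wid in enumerate(ps.word_ids):
            rows.append(
                {
                    "sample_index": s,
                    "word_id": wid,
                    "dim1": ps.samples[s, w, 0],
                    "dim2": ps.samples[s, w, 1],
                }
            )
    return pd.DataFrame(rows)


def deltas_to_frame(ps: PosteriorSamples) -> pd.DataFrame:
    rows = []
    for s in range(ps.n_samples):
        for p, pid in enumerate(ps.participant_ids):
            rows.append(
                {"sample_index": s, "participant_id": pid, "delta": ps.deltas[s, p]}
            )
    return pd.DataFrame(rows)
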