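"""Synthetic stimuli, renderings, and simulated observers.

This module generates everything the human face-pair arrangement experiment
produced, so the full analysis pipeline can be exercised and validated
without proprietary morphable-model data:

* a :class:`GenerativeMap` — deterministic affine maps from latent face
  coordinates to a 3-D mesh (with a landmark subset) and to pixel values,
  standing in for the morphable model's rendering pipeline.  Its linear
  parts have singular values decaying as 1/(1+index), so low-index latent
  dimensions matter most, as in a PCA-ordered face model;
* paired stimulus sets A and B that share the same pair geometries but use
  independent latent directions;
* simulated observers: perceived dissimilarity is a saturating sigmoid of a
  generating model's distance, to which each participant adds a stable
  idiosyncratic offset and each session adds fresh placement noise on the
  [0, 1] screen scale (then clipped to the screen).  Each trial carries a
  "same identity" line; the binary same/different label is re-derived from
  the placed line, so labels and continuous judgments are consistent by
  construction, exactly as the arrangement task enforces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .facespace import (
    FacePairStimulus,
    GeometricDesign,
    LatentVector,
    euclidean_distance,
    sample_pair,
)

__all__ = [
    "GenerativeMap",
    "ObserverSpec",
    "JudgmentDataset",
    "make_generative_map",
    "partition_trials",
    "simulate_observer",
    "make_paired_stimulus_sets",
    "weighted_distances",
    "calibrate_noise",
    "between_participant_correlation",
    "between_session_correlation",
]


def logistic_response(x, lo, hi, x0, k):
    """Four-parameter logistic lo + (hi-lo)/(1+exp(-k(x-x0))).

    Shared by the simulator (forward direction: distance -> placement) and
    the psychometric fit in :mod:`facesim.evaluation`.
    """
    from scipy.special import expit

    x = np.asarray(x, dtype=float)
    return lo + (hi - lo) * expit(k * (x - x0))


# ---------------------------------------------------------------------------
# Generative map (synthetic rendering pipeline)


@dataclass
class GenerativeMap:
    """Affine latent -> mesh / landmarks / image maps with a base face."""

    dim_latent: int
    n_landmarks: int
    n_mesh_vertices: int
    image_size: int
    W_mesh: np.ndarray  # (3*n_mesh_vertices, dim_latent)
    base_mesh: np.ndarray  # (3*n_mesh_vertices,)
    W_image: np.ndarray  # (image_size**2, dim_latent)
    base_image: np.ndarray  # (image_size**2,)
    seed: int | None = None

    def mesh(self, coords) -> np.ndarray:
        """Mesh vertex coordinates, shape (n_mesh_vertices, 3)."""
        x = np.asarray(coords, dtype=float)
        return (self.base_mesh + self.W_mesh @ x).reshape(self.n_mesh_vertices, 3)

    def landmarks(self, coords) -> np.ndarray:
        """Keypoint coordinates: the first n_landmarks mesh vertices."""
        return self.mesh(coords)[: self.n_landmarks]

    def image(self, coords) -> np.ndarray:
        """Flat pixel vector of length image_size**2."""
        x = np.asarray(coords, dtype=float)
        return self.base_image + self.W_image @ x


def make_generative_map(
    dim_latent: int = 398,
    n_landmarks: int = 30,
    image_size: int = 32,
    seed=None,
    n_mesh_vertices: int = 150,
) -> GenerativeMap:
    """Build a reproducible synthetic rendering map.

    Columns of each linear map are scaled by 1/(1+j) over the latent index j.
    The image map uses an orthonormal column basis (QR of a Gaussian matrix)
    when the pixel count allows, making its singular values exactly the
    decay profile; the mesh map uses unit-normalized Gaussian columns.
    """
    if dim_latent < 1 or n_landmarks < 3 or image_size < 1:
        raise ValueError("invalid generative-map dimensions")
    if n_mesh_vertices < n_landmarks:
        raise ValueError("mesh must contain at least n_landmarks vertices")
    rng = np.random.default_rng(seed)
    decay = 1.0 / (1.0 + np.arange(dim_latent))

    p = image_size * image_size
    G = rng.standard_normal((p, dim_latent))
    if p >= dim_latent:
        Q, _ = np.linalg.qr(G)
        W_image = Q * decay
    else:
        W_image = G / np.linalg.norm(G, axis=0) * decay
    base_image = rng.standard_normal(p)

    q = 3 * n_mesh_vertices
    H = rng.standard_normal((q, dim_latent))
    W_mesh = H / np.linalg.norm(H, axis=0) * decay
    base_mesh = 10.0 * rng.standard_normal(q)

    return GenerativeMap(
        dim_latent=dim_latent,
        n_landmarks=n_landmarks,
        n_mesh_vertices=n_mesh_vertices,
        image_size=image_size,
        W_mesh=W_mesh,
        base_mesh=base_mesh,
        W_image=W_image,
        base_image=base_image,
        seed=None if seed is None else int(seed),
    )


# ---------------------------------------------------------------------------
# Observer specification and judgment data


@dataclass
class ObserverSpec:
    """Parameters of the simulated observer population.

    The psychometric transform maps a generating model's distance d to a
    mean placement lo + (hi-lo)/(1+exp(-k(d-x0))) on the [0,1] screen scale.
    ``participant_sd`` is the SD of a per-(participant, pair) offset that is
    stable across sessions (individual idiosyncrasy); ``noise_sd`` is the SD
    of fresh per-session placement noise.  The defaults reproduce the target
    reliabilities of the arrangement task (between-participant correlation
    ~= 0.80 on session-averaged data, between-session correlation ~= 0.85)
    for the default 232-pair design under the analytic calibration in
    :func:`calibrate_noise`.
    """

    generating_model: str = "bfm_euclidean"
    lo: float = 0.05
    hi: float = 0.90
    x0: float = 25.0
    k: float = 0.10
    noise_sd: float = 0.111
    participant_sd: float = 0.095
    identity_tau: float = 0.55
    line_noise_sd: float = 0.02
    n_participants: int = 26
    n_sessions: int = 2
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError("need 0 <= lo < hi <= 1")
        if self.k <= 0:
            raise ValueError("sigmoid slope k must be positive")
        if self.noise_sd < 0 or self.participant_sd < 0 or self.line_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not (0.0 <= self.identity_tau <= 1.0):
            raise ValueError("identity threshold must lie in [0, 1]")
        if self.n_participants < 1 or self.n_sessions < 1:
            raise ValueError("need at least one participant and session")

    def true_dissimilarity(self, distances) -> np.ndarray:
        return logistic_response(distances, self.lo, self.hi, self.x0, self.k)


class JudgmentDataset:
    """Participant x session x pair dissimilarity and identity judgments.

    Wraps a long-format DataFrame with columns participant_id, session,
    set_label, trial, pair_id, dissimilarity, same_identity, identity_line.
    Invariants (validated on construction): dissimilarities in [0, 1]; the
    same/different flag equals (dissimilarity < that trial's identity line);
    every pair appears exactly once per participant-session; the identity
    line is constant within a trial.
    """

    COLUMNS = (
        "participant_id",
        "session",
        "set_label",
        "trial",
        "pair_id",
        "dissimilarity",
        "same_identity",
        "identity_line",
    )

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"judgment table is missing columns {missing}")
        self.frame = frame.reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.frame
        bad = ~df["dissimilarity"].between(0.0, 1.0)
        if bad.any():
            raise ValueError(
                f"dissimilarity outside [0, 1] at row {int(np.flatnonzero(bad)[0])}"
            )
        bad = ~df["identity_line"].between(0.0, 1.0)
        if bad.any():
            raise ValueError(
                f"identity line outside [0, 1] at row {int(np.flatnonzero(bad)[0])}"
            )
        expect = (df["dissimilarity"] < df["identity_line"]).astype(int)
        bad = df["same_identity"].astype(int) != expect
        if bad.any():
            raise ValueError(
                "same_identity flag inconsistent with identity line at row "
                f"{int(np.flatnonzero(bad)[0])}"
            )
        dup = df.duplicated(["participant_id", "session", "pair_id"])
        if dup.any():
            raise ValueError(
                f"pair repeated within a session at row {int(np.flatnonzero(dup)[0])}"
            )
        nline = df.groupby(["participant_id", "session", "trial"])["identity_line"].nunique()
        if (nline > 1).any():
            raise ValueError("identity line varies within a trial")

    # -- convenience accessors -------------------------------------------
    @property
    def participants(self) -> list:
        return sorted(self.frame["participant_id"].unique())

    @property
    def pair_ids(self) -> np.ndarray:
        return np.sort(self.frame["pair_id"].unique())

    @property
    def sessions(self) -> list:
        return sorted(self.frame["session"].unique())

    def session(self, s) -> "JudgmentDataset":
        return JudgmentDataset(self.frame[self.frame["session"] == s], validate=False)

    def pair_by_participant(self) -> pd.DataFrame:
        """Pairs x participants matrix of session-averaged dissimilarities."""
        return self.frame.pivot_table(
            index="pair_id", columns="participant_id", values="dissimilarity", aggfunc="mean"
        )

    def mean_dissimilarity(self) -> pd.Series:
        """Per-pair dissimilarity averaged over participants and sessions."""
        return self.frame.groupby("pair_id")["dissimilarity"].mean()


# ---------------------------------------------------------------------------
# Operations


def partition_trials(pair_ids: Iterable, per_trial: int = 8, seed=None) -> pd.Series:
    """Randomly partition pairs into disjoint trials of ``per_trial`` pairs.

    Returns a Series mapping pair_id -> trial index.  The number of pairs
    must divide exactly (the 232-pair design splits into 29 trials of 8).
    """
    ids = np.asarray(list(pair_ids))
    if per_trial < 1:
        raise ValueError("per_trial must be positive")
    if ids.size % per_trial != 0:
        raise ValueError(
            f"{ids.size} pairs cannot be split into trials of {per_trial}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    perm = rng.permutation(ids.size)
    trial = np.empty(ids.size, dtype=int)
    trial[perm] = np.arange(ids.size) // per_trial
    return pd.Series(trial, index=pd.Index(ids, name="pair_id"), name="trial")


def simulate_observer(
    spec: ObserverSpec,
    model_distances: pd.Series,
    trials: pd.Series,
    set_label: str = "A",
    participant_ids: Sequence | None = None,
    rng=None,
    participant_bias: pd.DataFrame | None = None,
) -> JudgmentDataset:
    """Simulate the arrangement task's output for one stimulus set.

    ``model_distances`` holds the generating model's distance per pair_id and
    ``trials`` the pair -> trial assignment.  ``participant_bias`` (pairs x
    participants) lets callers reuse the stable idiosyncratic offsets across
    sessions simulated in separate calls; by default fresh offsets are drawn
    here and shared across this call's sessions.
    """
    d = pd.Series(model_distances).astype(float)
    trials = pd.Series(trials)
    if not d.index.equals(trials.index):
        trials = trials.reindex(d.index)
        if trials.isna().any():
            raise ValueError("trial assignment does not cover all pairs")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_pairs = d.size
    if participant_ids is None:
        participant_ids = [f"p{i:02d}" for i in range(spec.n_participants)]
    true = spec.true_dissimilarity(d.to_numpy())
    trial_of_pair = trials.to_numpy()
    trial_ids = np.unique(trial_of_pair)

    if participant_bias is None:
        bias = {
            p: rng.normal(0.0, spec.participant_sd, n_pairs) for p in participant_ids
        }
    else:
        bias = {p: participant_bias[p].reindex(d.index).to_numpy() for p in participant_ids}

    records = []
    for p in participant_ids:
        for s in range(1, spec.n_sessions + 1):
            y = np.clip(true + bias[p] + rng.normal(0.0, spec.noise_sd, n_pairs), 0.0, 1.0)
            lines = np.clip(
                spec.identity_tau + rng.normal(0.0, spec.line_noise_sd, trial_ids.size),
                0.0,
                1.0,
            )
            line_of_pair = lines[np.searchsorted(trial_ids, trial_of_pair)]
            records.append(
                pd.DataFrame(
                    {
                        "participant_id": p,
                        "session": s,
                        "set_label": set_label,
                        "trial": trial_of_pair,
                        "pair_id": d.index.to_numpy(),
                        "dissimilarity": y,
                        "same_identity": (y < line_of_pair).astype(int),
                        "identity_line": line_of_pair,
                    }
                )
            )
    return JudgmentDataset(pd.concat(records, ignore_index=True))


def make_paired_stimulus_sets(
    design: GeometricDesign, dim: int = 398, seeds: tuple = (0, 1)
) -> tuple[list[FacePairStimulus], list[FacePairStimulus]]:
    """Two stimulus sets sharing the design's geometry with independent
    latent directions (sets A and B of the experiment)."""
    s1, s2 = seeds
    if s1 == s2:
        raise ValueError("the two stimulus sets need distinct seeds")
    out = []
    for label, seed in (("A", s1), ("B", s2)):
        rng = np.random.default_rng(seed)
        stims = []
        for pid, g in enumerate(design):
            v1, v2 = sample_pair(g, dim=dim, seed=rng)
            stims.append(FacePairStimulus(pid, g, v1, v2, set_label=label))
        out.append(stims)
    return out[0], out[1]


def weighted_distances(stimuli: Sequence[FacePairStimulus], weights) -> pd.Series:
    """Axis-weighted Euclidean distances ||w * (v1 - v2)|| per pair.

    Models an anisotropic observer whose perceptual metric stretches some
    latent axes relative to others.
    """
    w = np.asarray(weights, dtype=float)
    vals = {
        s.pair_id: float(np.linalg.norm(w * (s.v1.coords - s.v2.coords))) for s in stimuli
    }
    out = pd.Series(vals)
    out.index.name = "pair_id"
    return out


def calibrate_noise(
    true_dissimilarities,
    r_between: float = 0.80,
    r_within: float = 0.85,
    n_sessions: int = 2,
) -> tuple[float, float]:
    """Analytic noise calibration to target reliabilities.

    With signal variance s2 = Var(true dissimilarity across pairs),
    participant-offset variance u and session-noise variance v, the
    between-session correlation for one participant is
    (s2+u)/(s2+u+v) and the between-participant correlation of
    session-averaged judgments (m sessions) is s2/(s2+u+v/m).  Solving for
    (u, v) at the requested targets gives the returned
    (participant_sd, session_sd).  Screen clipping slightly shrinks both
    signal and noise, so realized reliabilities sit within a few hundredths
    of the targets for sigmoids that keep most mass inside [0, 1].
    """
    if not (0 < r_between <= r_within < 1):
        raise ValueError("need 0 < r_between <= r_within < 1")
    s2 = float(np.var(np.asarray(true_dissimilarities, dtype=float)))
    if s2 <= 0:
        raise ValueError("true dissimilarities have zero variance")
    m = n_sessions
    # From r_within = (s2+u)/(s2+u+v):      v = (s2+u)(1-r_w)/r_w
    # From r_between = s2/(s2+u+v/m):       s2 = r_b (s2+u)(1 + (1-r_w)/(m r_w))
    su = s2 / (r_between * (1.0 + (1.0 - r_within) / (m * r_within)))
    u = max(su - s2, 0.0)
    v = su * (1.0 - r_within) / r_within
    return float(np.sqrt(u)), float(np.sqrt(v))


def between_participant_correlation(dataset: JudgmentDataset) -> float:
    """Mean pairwise Pearson correlation between participants'
    session-averaged per-pair judgments."""
    mat = dataset.pair_by_participant()
    c = mat.corr().to_numpy()
    iu = np.triu_indices_from(c, k=1)
    return float(np.nanmean(c[iu]))


def between_session_correlation(dataset: JudgmentDataset) -> float:
    """Mean over participants of the Pearson correlation of their per-pair
    judgments between consecutive sessions."""
    sessions = dataset.sessions
    if len(sessions) < 2:
        raise ValueError("need at least two sessions")
    rs = []
    for p in dataset.participants:
        sub = dataset.frame[dataset.frame["participant_id"] == p]
        piv = sub.pivot_table(index="pair_id", columns="session", values="dissimilarity")
        for a, b in zip(sessions[:-1], sessions[1:]):
            rs.append(piv[a].corr(piv[b]))
    return float(np.nanmean(rs))
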