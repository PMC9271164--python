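"""Isotropy and uniformity of perceived dissimilarity in face space.

A perceptual metric over a latent face space is *isotropic* if judgments
depend only on the pair's geometry relative to the origin (r1, r2, theta),
not on the direction of the face vectors.  With two stimulus sets that share
geometries but differ in latent direction, isotropy predicts that each
participant's judgments correlate equally well between two sessions of the
same set and between sets; an anisotropic observer shows higher within-set
correlation.

The space is *uniform* if judgments depend only on the Euclidean distance
between the faces.  The uniformity test bins pairs by distance and asks, via
a within-bin regression of mean dissimilarity on angle (partialling out the
residual distance variation within the bin), whether angle carries extra
information; per-bin p-values are combined by Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .facespace import GeometricDesign
from .synthetic_data import JudgmentDataset

__all__ = ["IsotropyReport", "UniformityReport", "isotropy_test", "uniformity_test"]


@dataclass
class IsotropyReport:
    per_participant: pd.DataFrame  # columns r_within, r_between_1, r_between_2
    mean_within: float
    mean_between: float
    t_statistic: float
    t_p_value: float
    wilcoxon_p_value: float


@dataclass
class UniformityReport:
    bin_edges: np.ndarray
    table: pd.DataFrame  # per bin: n_pairs, slope, ci_low, ci_high, p_value
    omnibus_p_value: float


def isotropy_test(
    dataset_a_s1: JudgmentDataset,
    dataset_a_s2: JudgmentDataset,
    dataset_b: JudgmentDataset,
    shared_participants=None,
) -> IsotropyReport:
    """Within-set vs between-set replicability of dissimilarity judgments.

    For each shared participant, Pearson correlations are computed between
    per-pair judgments of (A session 1, A session 2), (A1, B) and (A2, B).
    One-tailed paired t and Wilcoxon tests ask whether the within-set
    correlation exceeds the mean of the two between-set correlations, the
    signature of anisotropy.
    """
    sets = [dataset_a_s1, dataset_a_s2, dataset_b]
    if shared_participants is None:
        shared = set(sets[0].participants)
        for ds in sets[1:]:
            shared &= set(ds.participants)
        shared_participants = sorted(shared)
    if len(shared_participants) < 6:
        raise ValueError("need at least 6 shared participants")
    ids = [set(ds.pair_ids) for ds in sets]
    if not (ids[0] == ids[1] == ids[2]):
        raise ValueError("datasets do not share the same pair geometry ids")

    mats = [ds.pair_by_participant() for ds in sets]
    rows = {}
    for p in shared_participants:
        a1, a2, b = (m[p] for m in mats)
        rows[p] = {
            "r_within": a1.corr(a2),
            "r_between_1": a1.corr(b),
            "r_between_2": a2.corr(b),
        }
    table = pd.DataFrame(rows).T
    table.index.name = "participant_id"
    within = table["r_within"].to_numpy()
    between = table[["r_between_1", "r_between_2"]].mean(axis=1).to_numpy()
    t_res = stats.ttest_rel(within, between, alternative="greater")
    diff = within - between
    if np.allclose(diff, 0.0):
        w_p = 1.0
    else:
        w_p = float(stats.wilcoxon(diff, alternative="greater").pvalue)
    return IsotropyReport(
        per_participant=table,
        mean_within=float(within.mean()),
        mean_between=float(between.mean()),
        t_statistic=float(t_res.statistic),
        t_p_value=float(t_res.pvalue),
        wilcoxon_p_value=w_p,
    )


def _bin_regression(sub: pd.DataFrame):
    """Partial slope of dissimilarity on theta within one distance bin."""
    y = sub["dissimilarity"].to_numpy()
    if np.ptp(y) < 1e-14 or sub["theta_deg"].nunique() < 2:
        return 0.0, 0.0, 0.0, 1.0
    X = sm.add_constant(sub[["distance", "theta_deg"]].to_numpy())
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[2])
    ci = fit.conf_int()[2]
    p = float(fit.pvalues[2])
    if not np.isfinite(p):
        p = 1.0
    return slope, float(ci[0]), float(ci[1]), p


def uniformity_test(
    dataset: JudgmentDataset, design: GeometricDesign, n_bins: int = 5
) -> UniformityReport:
    """Does angle explain dissimilarity variance at matched distances?

    Pairs are split into equal-count Euclidean-distance bins (bins are
    reduced until every bin holds at least 10 pairs, else an error).  Within
    each bin the mean dissimilarity is regressed on angle with the residual
    distance variation as a covariate; Fisher's method combines the per-bin
    angle p-values into an omnibus p.
    """
    frame = design.to_frame().set_index("pair_id")
    frame["distance"] = [g.euclidean for g in design]
    y = dataset.mean_dissimilarity()
    frame = frame.join(y.rename("dissimilarity"), how="inner")
    if frame["dissimilarity"].isna().any():
        raise ValueError("dataset does not cover the design")

    while n_bins >= 1:
        binned, edges = pd.qcut(
            frame["distance"], n_bins, retbins=True, duplicates="drop", labels=False
        )
        counts = binned.value_counts()
        if counts.min() >= 10:
            break
        n_bins -= 1
    else:
        raise ValueError("cannot form bins with at least 10 pairs each")

    rows = []
    pvals = []
    for b in sorted(counts.index):
        sub = frame[binned == b]
        slope, lo, hi, p = _bin_regression(sub)
        rows.append(
            {
                "bin": int(b),
                "n_pairs": int(len(sub)),
                "slope": slope,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p,
            }
        )
        pvals.append(p)
    omnibus = float(stats.combine_pvalues(pvals, method="fisher").pvalue)
    return UniformityReport(
        bin_edges=np.asarray(edges), table=pd.DataFrame(rows).set_index("bin"), omnibus_p_value=omnibus
    )
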