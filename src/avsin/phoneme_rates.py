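"""Per-phoneme identification rates by face type and their comparisons.

For each scored trial, a stimulus phoneme occurrence counts as *identified*
when it is matched in the response under minimum-multiplicity counting (the
same rule as the Jaccard intersection). Counts are accumulated per phoneme x
face type x participant; comparisons between face types pool counts across
participants (two-proportion z tests, Bonferroni-corrected across the tested
phonemes), and the four-phoneme group analysis pairs participants in a
paired-samples t test.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

#: The phonemes with the characteristic teeth/lip/tongue interactions that
#: synthetic faces render poorly (dental and labiodental fricatives).
DENTAL_LABIODENTAL = ("TH", "DH", "F", "V")

_FACE_OF_FORMAT = {"An": "An", "AnV_Real": "Real", "AnV_FACS": "FACS", "AnV_DNN": "DNN"}


def count_identifications(scored: pd.DataFrame) -> pd.DataFrame:
    """Accumulate per-phoneme identification counts.

    Parameters
    ----------
    scored
        Scored-trial table with ``stimulus_phonemes`` / ``response_phonemes``
        columns (space-separated ARPAbet). Catch trials are excluded; noisy
        formats map to face types An/Real/FACS/DNN.

    Returns
    -------
    DataFrame
        One row per (phoneme, face_type, participant) with ``n_identified``
        and ``n_presented`` (identified <= presented), plus ``rate``.
    """
    acc: Counter = Counter()
    pres: Counter = Counter()
    noisy = scored[scored["format"].isin(_FACE_OF_FORMAT)]
    for row in noisy.itertuples(index=False):
        face = _FACE_OF_FORMAT[row.format]
        stim = Counter(str(row.stimulus_phonemes).split())
        resp = Counter(str(row.response_phonemes).split())
        for p, n_stim in stim.items():
            key = (p, face, row.participant)
            pres[key] += n_stim
            acc[key] += min(n_stim, resp.get(p, 0))
    rows = [
        {
            "phoneme": p,
            "face_type": f,
            "participant": part,
            "n_identified": acc[(p, f, part)],
            "n_presented": n,
        }
        for (p, f, part), n in sorted(pres.items())
    ]
    table = pd.DataFrame(rows)
    table["rate"] = table["n_identified"] / table["n_presented"]
    return table


def _pooled(rates: pd.DataFrame, faces: list[str]) -> pd.DataFrame:
    """Pool counts across participants: one row per phoneme x face type."""
    sub = rates[rates["face_type"].isin(faces)]
    pooled = (
        sub.groupby(["phoneme", "face_type"])[["n_identified", "n_presented"]]
        .sum()
        .reset_index()
    )
    pooled["rate"] = pooled["n_identified"] / pooled["n_presented"]
    return pooled


def _difference_table(
    rates: pd.DataFrame,
    faces_a: list[str],
    faces_b: list[str],
    label_a: str,
    label_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-phoneme rate difference (A - B) with Bonferroni-corrected z tests.

    Rates for multi-face sides (e.g. synthetic = mean of DNN and FACS) are
    the unweighted mean of the per-face pooled rates, matching how the two
    synthetic formats are averaged; the significance test pools raw counts.
    """
    rows = []
    for phoneme, sub in rates.groupby("phoneme"):
        by_face = sub.groupby("face_type")[["n_identified", "n_presented"]].sum()
        if not all(f in by_face.index for f in faces_a + faces_b):
            logger.warning("phoneme %s missing a face type; excluded", phoneme)
            continue
        rate_a = float(np.mean([by_face.loc[f, "n_identified"] / by_face.loc[f, "n_presented"] for f in faces_a]))
        rate_b = float(np.mean([by_face.loc[f, "n_identified"] / by_face.loc[f, "n_presented"] for f in faces_b]))
        ka = int(by_face.loc[faces_a, "n_identified"].sum())
        na = int(by_face.loc[faces_a, "n_presented"].sum())
        kb = int(by_face.loc[faces_b, "n_identified"].sum())
        nb = int(by_face.loc[faces_b, "n_presented"].sum())
        if min(na, nb) == 0:
            continue
        try:
            z, p = proportions_ztest([ka, kb], [na, nb])
            if not np.isfinite(p):
                p = 1.0
        except Exception:
            z, p = 0.0, 1.0
        rows.append(
            {
                "phoneme": phoneme,
                f"{label_a}_rate": rate_a,
                f"{label_b}_rate": rate_b,
                "difference": rate_a - rate_b,
                "z": float(z),
                "p_raw": float(p),
            }
        )
    columns = ["phoneme", f"{label_a}_rate", f"{label_b}_rate",
               "difference", "z", "p_raw"]
    table = pd.DataFrame(rows, columns=columns)
    m = len(table)
    table["adjusted_p"] = np.clip(table["p_raw"] * m, 0.0, 1.0)
    table["significant"] = table["adjusted_p"] < alpha
    return table.sort_values("difference", ascending=False).reset_index(drop=True)


def real_synthetic_differences(rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-phoneme Real minus Synthetic (mean of DNN and FACS) differences.

    Auditory-only rows are ignored; the returned table is sorted by
    descending difference and carries Bonferroni-adjusted p-values with the
    family size equal to the number of phonemes tested.
    """
    return _difference_table(rates, ["Real"], ["DNN", "FACS"], "real", "synthetic", alpha)


def dnn_vs_facs(rates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-phoneme DNN minus FACS differences (positive = DNN better)."""
    return _difference_table(rates, ["DNN"], ["FACS"], "dnn", "facs", alpha)


def _participant_group_means(
    rates: pd.DataFrame, faces: list[str], group: set[str]
) -> pd.DataFrame:
    """Per-participant mean rate over group phonemes and over the rest.

    A participant's rate for a phoneme within the face category pools that
    participant's counts over the included face types; the group mean is the
    unweighted mean over phonemes (each phoneme contributes equally).
    """
    sub = rates[rates["face_type"].isin(faces)]
    per = (
        sub.groupby(["participant", "phoneme"])[["n_identified", "n_presented"]]
        .sum()
        .reset_index()
    )
    per["rate"] = per["n_identified"] / per["n_presented"]
    per["in_group"] = per["phoneme"].isin(group)
    wide = per.groupby(["participant", "in_group"])["rate"].mean().unstack()
    wide.columns = ["rest_mean" if not c else "group_mean" for c in wide.columns]
    return wide.dropna()


def group_contrast(
    rates: pd.DataFrame, group: tuple[str, ...] = DENTAL_LABIODENTAL
) -> pd.DataFrame:
    """Paired-t contrast of a phoneme group against all other phonemes.

    For each face category (Real; Synthetic = DNN+FACS pooled; and their
    per-participant difference) the group mean and rest mean are computed per
    participant and compared with a paired-samples t test.

    Returns a DataFrame with one row per measure: group/rest means, t, df,
    two-tailed p, and n participants.
    """
    group_set = set(group)
    real = _participant_group_means(rates, ["Real"], group_set)
    synth = _participant_group_means(rates, ["DNN", "FACS"], group_set)
    results = []
    joined = real.join(synth, lsuffix="_real", rsuffix="_synth", how="inner")
    if len(joined) < 3:
        raise ValueError("need at least 3 participants with group and rest means")
    for measure, g, r in (
        ("Real", joined["group_mean_real"], joined["rest_mean_real"]),
        ("Synthetic", joined["group_mean_synth"], joined["rest_mean_synth"]),
        (
            "Real_minus_Synthetic",
            joined["group_mean_real"] - joined["group_mean_synth"],
            joined["rest_mean_real"] - joined["rest_mean_synth"],
        ),
    ):
        if np.allclose(g - r, (g - r).iloc[0]):
            # zero-variance differences: t undefined
            raise ValueError(f"degenerate paired differences for {measure}")
        t, p = stats.ttest_rel(g, r)
        results.append(
            {
                "measure": measure,
                "group_mean": float(g.mean()),
                "rest_mean": float(r.mean()),
                "t": float(t),
                "df": len(g) - 1,
                "p": float(p),
                "n_participants": len(g),
            }
        )
    return pd.DataFrame(results)


def pooled_rates(rates: pd.DataFrame) -> pd.DataFrame:
    """Pooled per-phoneme rates for each face type (An, Real, DNN, FACS)."""
    return _pooled(rates, sorted(rates["face_type"].unique()))
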