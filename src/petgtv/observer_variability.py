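"""Inter- and intra-observer agreement statistics for delineation studies.

Definitions used here (all standard in contour-comparison work):

* **reliability index** of K observers' masks — the *generalized
  conformity index*: common volume over composite volume,
  vol(∩ masks) / vol(∪ masks).  1 means perfect agreement; it is the
  strictest multi-observer overlap (never above any pairwise Jaccard).
  An alternative convention (mean pairwise Jaccard) is available via
  ``pairwise_jaccard_mean``.
* **intra-observer concordance** — the Jaccard index of one observer's
  two delineation sessions.
* **ratio_max_min** — largest over smallest delineated volume per
  patient, summarized across the cohort by median and range.
* **two-way ANOVA** on log volumes with fixed factors patient and
  observer; with two sessions per cell the residual captures the
  intra-observer variation.  Volumes are positive with multiplicative
  error, hence the log transform.
* **modality comparison** — paired t-test and exact Wilcoxon
  signed-rank on per-patient volumes; both are reported and neither is
  privileged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .voxel_core import BinaryMask, StructureSet, composite_and_common, volume

__all__ = [
    "VariabilityReport",
    "reliability_index",
    "pairwise_jaccard_mean",
    "intra_concordance",
    "ratio_max_min",
    "anova_two_way",
    "compare_modalities",
    "variability_report",
]


def reliability_index(masks: Sequence[BinaryMask]) -> float:
    """Generalized conformity index: vol(common) / vol(composite)."""
    composite, common = composite_and_common(masks)
    v_comp = composite.n_voxels
    if v_comp == 0:
        raise ValueError("all masks are empty; reliability index undefined")
    return common.n_voxels / v_comp


def pairwise_jaccard_mean(masks: Sequence[BinaryMask]) -> float:
    """Mean Jaccard index over all unordered mask pairs (alternative convention)."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    vals = []
    for a, b in itertools.combinations(masks, 2):
        vals.append(intra_concordance(a, b))
    return float(np.mean(vals))


def intra_concordance(session1: BinaryMask, session2: BinaryMask) -> float:
    """Jaccard index vol(∩)/vol(∪) of one observer's two sessions."""
    if not session1.same_geometry(session2):
        from .voxel_core import GeometryError

        raise GeometryError("sessions do not share a geometry")
    n_union = int(np.count_nonzero(session1.values | session2.values))
    if n_union == 0:
        raise ValueError("both sessions empty; concordance undefined")
    n_inter = int(np.count_nonzero(session1.values & session2.values))
    return n_inter / n_union


def ratio_max_min(volumes: Sequence[float]) -> float:
    """Largest-to-smallest volume ratio (≥ 1; 1 iff all equal)."""
    vols = np.asarray(list(volumes), dtype=float)
    if len(vols) < 2:
        raise ValueError("need at least 2 volumes")
    if np.any(vols <= 0):
        raise ValueError("volumes must be positive")
    return float(vols.max() / vols.min())


def anova_two_way(table: pd.DataFrame) -> dict:
    """Two-way fixed-effects ANOVA of log volume on patient and observer.

    Parameters
    ----------
    table : DataFrame
        Columns ``patient``, ``observer``, ``volume_cm3`` (one row per
        session replicate).  The crossed design must be complete: every
        patient × observer cell needs at least one value.

    Returns
    -------
    dict with ``F_observer``, ``p_observer``, ``F_patient``,
    ``p_patient`` (and degrees of freedom).  With two sessions per cell
    the residual mean square estimates the intra-observer variance of
    log volume.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table.copy()
    required = {"patient", "observer", "volume_cm3"}
    if not required.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if np.any(df["volume_cm3"].to_numpy(dtype=float) <= 0):
        raise ValueError("volumes must be positive for the log transform")
    counts = df.groupby(["patient", "observer"]).size().unstack(fill_value=0)
    if (counts.to_numpy() == 0).any():
        raise ValueError("incomplete crossed design: some patient × observer cell is empty")
    df["log_volume"] = np.log(df["volume_cm3"].astype(float))
    if np.isclose(df["log_volume"].var(ddof=0), 0.0):
        raise ValueError("zero total variance; ANOVA undefined")
    model = ols("log_volume ~ C(patient) + C(observer)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    return {
        "F_patient": float(aov.loc["C(patient)", "F"]),
        "p_patient": float(aov.loc["C(patient)", "PR(>F)"]),
        "F_observer": float(aov.loc["C(observer)", "F"]),
        "p_observer": float(aov.loc["C(observer)", "PR(>F)"]),
        "df_patient": float(aov.loc["C(patient)", "df"]),
        "df_observer": float(aov.loc["C(observer)", "df"]),
        "df_residual": float(aov.loc["Residual", "df"]),
        "residual_ms": float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"]),
    }


def compare_modalities(
    volumes_ct: Sequence[float], volumes_petct: Sequence[float]
) -> dict:
    """Paired comparison of per-patient volumes between two modalities.

    Reports the two-sided paired t-test and the exact Wilcoxon
    signed-rank test.  ``mean_diff`` is mean(ct) − mean(petct).  If all
    paired differences are zero the Wilcoxon statistic is undefined and
    flagged with ``wilcoxon_defined=False``.
    """
    a = np.asarray(list(volumes_ct), dtype=float)
    b = np.asarray(list(volumes_petct), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    if np.allclose(diff, 0.0):
        t_stat, p_t = 0.0, 1.0
        return {
            "t_statistic": t_stat,
            "p_t": p_t,
            "wilcoxon_statistic": float("nan"),
            "p_w": float("nan"),
            "wilcoxon_defined": False,
            "mean_diff": 0.0,
            "n": int(len(a)),
        }
    t_res = stats.ttest_rel(a, b)
    w_res = stats.wilcoxon(a, b, zero_method="wilcox", method="exact")
    return {
        "t_statistic": float(t_res.statistic),
        "p_t": float(t_res.pvalue),
        "wilcoxon_statistic": float(w_res.statistic),
        "p_w": float(w_res.pvalue),
        "wilcoxon_defined": True,
        "mean_diff": float(diff.mean()),
        "n": int(len(a)),
    }


@dataclass
class VariabilityReport:
    """Observer-agreement statistics per patient × modality plus cohort rollups."""

    per_patient: pd.DataFrame = field(default_factory=pd.DataFrame)
    cohort: dict = field(default_factory=dict)
    anova: dict = field(default_factory=dict)
    paired_tests: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_patient": self.per_patient.to_dict(orient="records"),
            "cohort": self.cohort,
            "anova": self.anova,
            "paired_tests": self.paired_tests,
        }


def _median_range(values: Sequence[float]) -> dict:
    arr = np.asarray(list(values), dtype=float)
    return {
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n": int(len(arr)),
    }


def variability_report(
    sset: StructureSet, modalities: Sequence[str] = ("CT", "PETCT")
) -> VariabilityReport:
    """Full observer-variability analysis of a session-1/session-2 structure set.

    Per patient × modality: the inter-observer reliability index over
    session-1 masks, each observer's intra-observer concordance
    (session 1 vs 2) and the max/min ratio of session-1 volumes.  Cohort
    level: medians and ranges, the two-way ANOVA per modality, and the
    paired CT vs PET/CT comparison of per-patient mean session-1
    volumes.
    """
    rows = []
    anova_tables: dict[str, list] = {m: [] for m in modalities}
    per_patient_mean_vol: dict[str, dict[str, float]] = {m: {} for m in modalities}

    for modality in modalities:
        entries = sset.select(modality=modality)
        patients = sorted({k[0] for k, _ in entries})
        for pat in patients:
            obs_ids = sorted({k[2] for k, _ in sset.select(patient_id=pat, modality=modality)})
            s1_masks = [sset.get(pat, modality, o, 1) for o in obs_ids]
            ri = reliability_index(s1_masks)
            vols1 = [volume(m) for m in s1_masks]
            concords = {}
            for o in obs_ids:
                try:
                    s2 = sset.get(pat, modality, o, 2)
                except KeyError:
                    continue
                concords[o] = intra_concordance(sset.get(pat, modality, o, 1), s2)
            row = {
                "patient": pat,
                "modality": modality,
                "reliability_index": ri,
                "ratio_max_min": ratio_max_min(vols1) if len(vols1) >= 2 else 1.0,
                "mean_volume_cm3": float(np.mean(vols1)),
            }
            for o, c in concords.items():
                row[f"intra_concordance_obs{o}"] = c
            row["intra_concordance_mean"] = (
                float(np.mean(list(concords.values()))) if concords else float("nan")
            )
            rows.append(row)
            per_patient_mean_vol[modality][pat] = float(np.mean(vols1))
            for (p, m, o, s), mask in sset.select(patient_id=pat, modality=modality):
                anova_tables[modality].append(
                    {"patient": p, "observer": o, "session": s, "volume_cm3": volume(mask)}
                )

    per_patient = pd.DataFrame(rows)
    cohort: dict = {}
    for modality in modalities:
        sub = per_patient[per_patient["modality"] == modality]
        if sub.empty:
            continue
        cohort[modality] = {
            "reliability_index": _median_range(sub["reliability_index"]),
            "intra_concordance": _median_range(sub["intra_concordance_mean"].dropna()),
            "ratio_max_min": _median_range(sub["ratio_max_min"]),
        }

    anova = {}
    for modality, recs in anova_tables.items():
        tab = pd.DataFrame(recs)
        if not tab.empty and tab["patient"].nunique() >= 2 and tab["observer"].nunique() >= 2:
            anova[modality] = anova_two_way(tab)

    paired = {}
    mods = list(modalities)
    if len(mods) >= 2:
        m1, m2 = mods[0], mods[1]
        common_pat = sorted(set(per_patient_mean_vol[m1]) & set(per_patient_mean_vol[m2]))
        if len(common_pat) >= 3:
            paired[f"{m1}_vs_{m2}"] = compare_modalities(
                [per_patient_mean_vol[m1][p] for p in common_pat],
                [per_patient_mean_vol[m2][p] for p in common_pat],
            )

    return VariabilityReport(
        per_patient=per_patient, cohort=cohort, anova=anova, paired_tests=paired
    )
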