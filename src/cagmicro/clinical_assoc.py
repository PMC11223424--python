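"""Associations between CAG abundances in tumor samples and clinical features.

All tests are rank-based (Mann-Whitney, Kruskal-Wallis, Spearman), so results
are invariant to marker unit rescaling. Missing clinical values are excluded
pairwise and the reported n is the count actually used. Raw p-values drive
the significance flag (at 0.05); BH-adjusted values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AbundanceTable, DataError, MARKERS
from .diff_abundance import TestResult, bh_fdr, kruskal_wallis, mann_whitney, spearman


@dataclass(frozen=True)
class ClinicalAssociation:
    cag_id: str
    variable: str
    kind: str            # binary_contrast | categorical_contrast | marker_correlation
    result: TestResult
    n_missing: int = 0


def _tt_profiles(profiles: AbundanceTable, meta: pd.DataFrame) -> AbundanceTable:
    tissue = meta.loc[profiles.samples, "tissue"]
    tt = [s for s in profiles.samples if tissue[s] == "TT"]
    if not tt:
        raise DataError("no tumor samples in profiles")
    return profiles.select_samples(tt)


def binary_contrast(profiles_tt: AbundanceTable, meta: pd.DataFrame,
                    variable: str) -> list[ClinicalAssociation]:
    """Mann-Whitney contrast of each CAG between the two levels of ``variable``.

    Per-level medians are reported in percent; samples with a missing value
    are excluded and counted.
    """
    values = meta.loc[profiles_tt.samples, variable]
    present = values.notna()
    levels = sorted(values[present].astype(str).unique())
    if len(levels) != 2:
        raise DataError(f"{variable!r} has {len(levels)} observed level(s); need exactly 2")
    out = []
    for cag in profiles_tt.taxa:
        row = profiles_tt.data.loc[cag]
        by_level = {lv: row[present.index[present & (values.astype(str) == lv)]].to_numpy()
                    for lv in levels}
        if any(len(v) == 0 for v in by_level.values()):
            raise DataError(f"{variable!r} level with zero samples")
        res = mann_whitney(by_level[levels[0]], by_level[levels[1]], feature=cag)
        medians = {lv: float(np.median(v) * 100) for lv, v in by_level.items()}
        res = TestResult(cag, res.test, res.statistic, res.p_value, medians,
                         n=res.n, extra={"median_scale": "percent"})
        out.append(ClinicalAssociation(cag, variable, "binary_contrast", res,
                                       n_missing=int((~present).sum())))
    return out


def categorical_contrast(profiles_tt: AbundanceTable, meta: pd.DataFrame,
                         variable: str) -> list[ClinicalAssociation]:
    """Kruskal-Wallis contrast across the observed levels (2 levels delegate
    to the binary contrast)."""
    values = meta.loc[profiles_tt.samples, variable]
    present = values.notna()
    levels = sorted(values[present].astype(str).unique())
    if len(levels) < 2:
        raise DataError(f"{variable!r} has fewer than 2 observed levels")
    if len(levels) == 2:
        return binary_contrast(profiles_tt, meta, variable)
    out = []
    for cag in profiles_tt.taxa:
        row = profiles_tt.data.loc[cag]
        groups = [row[present.index[present & (values.astype(str) == lv)]].to_numpy()
                  for lv in levels]
        res = kruskal_wallis(groups, feature=cag)
        medians = {lv: float(np.median(g) * 100) for lv, g in zip(levels, groups)}
        res = TestResult(cag, res.test, res.statistic, res.p_value, medians,
                         n=res.n, extra={"median_scale": "percent"})
        out.append(ClinicalAssociation(cag, variable, "categorical_contrast", res,
                                       n_missing=int((~present).sum())))
    return out


def marker_correlations(profiles_tt: AbundanceTable, meta: pd.DataFrame,
                        markers=MARKERS) -> list[ClinicalAssociation]:
    """Spearman correlation of each CAG with each numeric tumor marker
    (pairwise-complete)."""
    out = []
    for marker in markers:
        vals = pd.to_numeric(meta.loc[profiles_tt.samples, marker], errors="coerce")
        for cag in profiles_tt.taxa:
            row = profiles_tt.data.loc[cag].to_numpy(dtype=float)
            res = spearman(row, vals.to_numpy(dtype=float), feature=cag)
            out.append(ClinicalAssociation(cag, marker, "marker_correlation", res,
                                           n_missing=len(vals) - res.n))
    return out


def association_table(assocs: list[ClinicalAssociation],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Long-format association table with raw and BH-adjusted p-values.

    ``significant`` uses the raw p-value at ``alpha``; adjustment is applied
    across the whole CAG × variable grid passed in.
    """
    rows = []
    for a in assocs:
        r = a.result
        rows.append({
            "cag": a.cag_id, "variable": a.variable, "kind": a.kind,
            "test": r.test, "statistic": r.statistic, "p_value": r.p_value,
            "n": r.n, "n_missing": a.n_missing,
            **{f"median_{k}": v for k, v in r.group_medians.items()},
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = bh_fdr(df["p_value"].to_numpy())
        df["significant"] = df["p_value"] < alpha
    return df


def associate(profiles: AbundanceTable, meta: pd.DataFrame,
              variables=("microsatellite", "stage", "ki67"),
              markers=MARKERS) -> pd.DataFrame:
    """Run the full clinical-association grid on tumor samples only."""
    tt = _tt_profiles(profiles, meta)
    assocs: list[ClinicalAssociation] = []
    for var in variables:
        if var not in meta.columns:
            continue
        observed = meta.loc[tt.samples, var].dropna()
        if observed.astype(str).nunique() < 2:
            continue  # uncontrastable in this cohort (e.g. no unstable tumors)
        assocs.extend(categorical_contrast(tt, meta, var))
    avail = [m for m in markers if m in meta.columns]
    if avail:
        assocs.extend(marker_correlations(tt, meta, avail))
    return association_table(assocs)
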