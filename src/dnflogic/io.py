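"""Panel file I/O.

Feature matrices are CSV/TSV with the sample id in the first column and
strictly 0/1 feature cells.  Response tables are long-format CSV/TSV with
columns ``sample_id, drug, value[, ci_low, ci_high]`` so that missing
measurements are simply absent rows; samples lacking a value for the
requested drug are dropped before fitting — no imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import SyntheticPanel

__all__ = ["load_feature_matrix", "load_output_table", "write_panel",
           "align_drug"]


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def load_feature_matrix(path):
    """Read a binary feature matrix.

    Returns (X int8 array, sample_ids, feature_names).  Non-binary cells and
    duplicate sample ids raise with the offending location named.
    """
    df = _read(path)
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    body = df.drop(columns=[id_col])
    for col in body.columns:
        vals = pd.to_numeric(body[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = ids[int(np.flatnonzero(bad)[0])]
            raise ValueError(
                f"non-binary feature value in column {col!r}, sample {row!r}")
        body[col] = vals
    return body.to_numpy(dtype=np.int8), ids, list(body.columns)


def load_output_table(path, drug: str | None = None):
    """Read a long-format response table, optionally restricted to one drug.

    Returns a DataFrame with columns sample_id, drug, value, ci_low, ci_high
    (CI columns NaN when absent from the file).
    """
    df = _read(path)
    required = {"sample_id", "drug", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"output table needs columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    for col in ("ci_low", "ci_high"):
        if col not in df.columns:
            df[col] = np.nan
    df["sample_id"] = df["sample_id"].astype(str)
    if drug is not None:
        sub = df[df["drug"] == drug]
        if sub.empty:
            raise ValueError(
                f"no measurements for drug {drug!r}; available: "
                f"{sorted(df['drug'].unique())[:20]}")
        return sub.reset_index(drop=True)
    return df


def align_drug(X, sample_ids, feature_names, output_df, drug: str):
    """Intersect the feature matrix with one drug's measured samples.

    Returns (X_sub, z, ci_low, ci_high, kept_sample_ids); samples without a
    measurement are dropped, never imputed.
    """
    sub = output_df[output_df["drug"] == drug] if "drug" in output_df else output_df
    sub = sub.dropna(subset=["value"])
    by_id = {r.sample_id: r for r in sub.itertuples()}
    keep, z, lo, hi = [], [], [], []
    for i, sid in enumerate(sample_ids):
        r = by_id.get(sid)
        if r is None:
            continue
        keep.append(i)
        z.append(r.value)
        lo.append(r.ci_low)
        hi.append(r.ci_high)
    if not keep:
        raise ValueError(f"no overlap between feature matrix and drug {drug!r}")
    keep = np.asarray(keep)
    return (np.asarray(X)[keep], np.asarray(z, dtype=float),
            np.asarray(lo, dtype=float), np.asarray(hi, dtype=float),
            [sample_ids[i] for i in keep])


def write_panel(panel: SyntheticPanel, features_path, response_path,
                drug: str = "synthetic_drug") -> None:
    """Write a synthetic panel as a feature matrix + long response table."""
    feat = pd.DataFrame(panel.X, columns=panel.feature_names)
    feat.insert(0, "sample_id", panel.sample_ids)
    feat.to_csv(features_path, index=False)

    measured = panel.measured
    resp = pd.DataFrame({
        "sample_id": [panel.sample_ids[i] for i in measured],
        "drug": drug,
        "value": panel.z[measured],
        "ci_low": panel.ci_low[measured],
        "ci_high": panel.ci_high[measured],
    })
    resp.to_csv(response_path, index=False)
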