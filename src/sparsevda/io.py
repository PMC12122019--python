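"""Reading delimited datasets and serializing fit results.

All floating point output uses repr-precision (17 significant digits) so
written tables round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.17g"


def read_dataset(path, label_column: str, delimiter: str = None):
    """Load a delimited file into (X, labels, feature_names).

    The delimiter is inferred from the extension (``.tsv`` -> tab,
    otherwise comma) unless given.  Non-numeric feature cells raise with
    their coordinates.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in "
                         f"{path} (columns: {list(df.columns)})")
    labels = df[label_column].to_numpy()
    features = df.drop(columns=[label_column])
    for col in features.columns:
        converted = pd.to_numeric(features[col], errors="coerce")
        bad = converted.isna() & features[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {features[col].iloc[row]!r} at row "
                f"{row}, column {col!r}")
        features[col] = converted
    if features.isna().any().any():
        raise ValueError("dataset contains missing feature values")
    return features.to_numpy(dtype=float), labels, list(features.columns)


def write_dataset(path, X, labels, label_column: str = "label",
                  feature_names=None, delimiter: str = None):
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    X = np.asarray(X)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=feature_names)
    df[label_column] = labels
    df.to_csv(path, sep=delimiter, index=False, float_format=FLOAT_FMT)
    return path


def _coef_frame(model):
    import pandas as pd

    coef = getattr(model, "coef_", None)
    if coef is None:
        coef = model.dual_coef_
    rows = [f"feature_{j}" for j in range(coef.shape[0])]
    frame = pd.DataFrame(coef, index=rows,
                         columns=[str(cl) for cl in model.classes_])
    frame.loc["intercept"] = model.intercept_
    return frame.reindex(["intercept"] + rows)


def write_fit(model, outdir, manifest: dict = None):
    """Serialize a fitted estimator: coefficients, support, JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _coef_frame(model).to_csv(outdir / "coefficients.csv",
                              float_format=FLOAT_FMT)
    support = getattr(model, "support_", None)
    if support is None:
        support = model.avatars_
    np.savetxt(outdir / "support.txt", support, fmt="%d")
    manifest = dict(manifest or {})
    manifest.update({
        "params": {key: _jsonable(val)
                   for key, val in model.get_params().items()},
        "classes": [str(cl) for cl in model.classes_],
        "support_size": int(len(support)),
        "converged": bool(getattr(model, "converged_", True)),
    })
    result = getattr(model, "fit_result_", None)
    if result is not None:
        manifest["rho_final"] = result.rho_final
        manifest["n_outer"] = result.n_outer
        manifest["n_inner_total"] = result.n_inner_total
        manifest["dist_trace"] = [float(v) for v in result.dist_trace]
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_jsonable))
    return outdir


def write_cv_result(result, outdir):
    """One-row replicate table plus a JSON summary for a CVResult."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    row = {"seed": result.seed, "eps": result.chosen_eps,
           "gamma": result.chosen_gamma, "k": result.chosen_k,
           "test_error_pct": result.test_error_pct,
           "support_size": len(result.support)}
    pd.DataFrame([row]).to_csv(outdir / "cv_result.csv", index=False,
                               float_format=FLOAT_FMT)
    write_fit(result.final_model, outdir, manifest={"cv": row})
    return outdir


def write_stability_report(report, outdir):
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report.replicates).to_csv(outdir / "replicates.csv",
                                           index=False,
                                           float_format=FLOAT_FMT)
    summary = {
        "n_repeats": report.n_repeats,
        "model_sizes": [int(s) for s in report.model_sizes],
        "size_quantiles_10_50_90": [float(v) for v in report.size_quantiles],
    }
    (outdir / "stability.json").write_text(
        json.dumps(summary, indent=2, default=_jsonable))
    np.savetxt(outdir / "feature_counts.txt", report.feature_counts,
               fmt="%d")
    if report.per_class_counts is not None:
        np.savetxt(outdir / "per_class_counts.txt", report.per_class_counts,
                   fmt="%d")
    return outdir


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value
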