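"""Readers and writers: delimited layers/outcomes and JSON model files.

Layers are delimited text with a header row of feature IDs and the sample
ID in the first column; outcomes carry columns sample_id, observed_age,
event.  ``.tsv``/``.txt`` files are tab-separated, everything else
comma-separated.  Sample alignment is always by ID with set equality
enforced -- row order on disk is never trusted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cooperative import CoopConfig, CoopModel
from .cox import FitOptions
from .data import DataLayer, OutcomeTable, StepCurve
from .exceptions import DataError

MODEL_FORMAT = "coophaz-model"
MODEL_VERSION = 1


def _sep(path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","


def _check_numeric(df: pd.DataFrame, path) -> np.ndarray:
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise DataError(
            f"{path}: non-numeric or missing cell at row '{df.index[r]}', "
            f"column '{df.columns[c]}'")
    return values


def read_layer(path, name: str | None = None) -> DataLayer:
    """Read one covariate layer from delimited text."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    ids = df.index.astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()][0]
        raise DataError(f"{path}: duplicated sample ID '{dup}'")
    values = _check_numeric(df, path)
    return DataLayer(name or Path(path).stem,
                     np.asarray(ids, dtype=object),
                     np.asarray(df.columns.astype(str), dtype=object),
                     values)


def read_outcome(path) -> OutcomeTable:
    """Read the outcome table (columns sample_id, observed_age, event)."""
    df = pd.read_csv(path, sep=_sep(path))
    for col in ("sample_id", "observed_age", "event"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column '{col}'")
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        raise DataError(f"{path}: duplicated sample ID "
                        f"'{ids[ids.duplicated()].iloc[0]}'")
    sub = df[["observed_age", "event"]]
    _check_numeric(sub.set_axis(ids), path)
    return OutcomeTable(np.asarray(ids, dtype=object),
                        df["observed_age"].to_numpy(dtype=float),
                        df["event"].to_numpy())


def align_layers(layers: list[DataLayer],
                 outcome: OutcomeTable) -> list[DataLayer]:
    """Reorder layer rows to the outcome's sample order (by ID)."""
    target = list(outcome.sample_id)
    out = []
    for layer in layers:
        have = set(layer.sample_id.tolist())
        want = set(target)
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            parts = []
            if missing:
                parts.append(f"missing samples {missing[:5]}")
            if extra:
                parts.append(f"unexpected samples {extra[:5]}")
            raise DataError(f"layer '{layer.name}': " + "; ".join(parts))
        pos = {sid: i for i, sid in enumerate(layer.sample_id)}
        out.append(layer.subset(np.array([pos[sid] for sid in target])))
    return out


def read_layers(paths, outcome: OutcomeTable | None = None
                ) -> list[DataLayer]:
    """Read several layers; align them to ``outcome`` when given."""
    layers = [read_layer(p) for p in paths]
    if outcome is not None:
        layers = align_layers(layers, outcome)
    return layers


def write_layer(layer: DataLayer, path) -> None:
    df = pd.DataFrame(layer.values, index=pd.Index(layer.sample_id,
                                                   name="sample_id"),
                      columns=layer.feature_id)
    df.to_csv(path, sep=_sep(path))


def write_outcome(outcome: OutcomeTable, path) -> None:
    pd.DataFrame({"sample_id": outcome.sample_id,
                  "observed_age": outcome.observed_age,
                  "event": outcome.event}).to_csv(path, sep=_sep(path),
                                                  index=False)


# ---------------------------------------------------------------------------
# model serialization


def model_to_dict(model: CoopModel) -> dict:
    """JSON-ready model layout (documented, versioned)."""
    cfg = model.config
    return {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "rho": cfg.rho,
        "lambda": cfg.lam,
        "pair_scheme": cfg.pair_scheme,
        "normalize_agreement": cfg.normalize_agreement,
        "lp_offset": model.lp_offset,
        "objective": model.objective,
        "layers": [
            {
                "name": name,
                "features": [str(f) for f in fid],
                "beta": cv.beta.tolist(),
                "normalized": bool(cv.normalized),
                "beta_hat": (None if model.beta_hats is None
                             else model.beta_hats[j].tolist()),
            }
            for j, (name, fid, cv) in enumerate(
                zip(model.layer_names, model.feature_ids,
                    model.coefficients))
        ],
        "baseline": {
            "knots": model.baseline.knots.tolist(),
            "values": model.baseline.values.tolist(),
        },
    }


def model_from_dict(doc: dict) -> CoopModel:
    if doc.get("format") != MODEL_FORMAT:
        raise DataError("not a coophaz model file")
    from .data import CoefficientVector
    coeffs, names, fids, bhats = [], [], [], []
    for entry in doc["layers"]:
        names.append(entry["name"])
        fids.append(np.asarray(entry["features"], dtype=object))
        coeffs.append(CoefficientVector(entry["name"],
                                        np.asarray(entry["beta"]),
                                        entry["normalized"]))
        bhats.append(None if entry.get("beta_hat") is None
                     else np.asarray(entry["beta_hat"]))
    baseline = StepCurve(np.asarray(doc["baseline"]["knots"]),
                         np.asarray(doc["baseline"]["values"]),
                         "cumulative_hazard")
    cfg = CoopConfig(rho=doc["rho"], lam=doc["lambda"],
                     pair_scheme=doc["pair_scheme"],
                     normalize_agreement=doc.get("normalize_agreement",
                                                 False),
                     fit_options=FitOptions())
    beta_hats = None if any(b is None for b in bhats) else bhats
    return CoopModel(coeffs, baseline, cfg, names, fids,
                     lp_offset=doc.get("lp_offset", 0.0),
                     objective=doc.get("objective"), beta_hats=beta_hats)


def save_model(model: CoopModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path) -> CoopModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# curve tables


def write_curves(curves, path) -> None:
    """Long-format curve table: sample_id, age, cumulative_hazard,
    survival (one row per knot per individual)."""
    rows = []
    for c in curves:
        for age, H, S in zip(c.hazard.knots, c.hazard.values,
                             c.survival.values):
            rows.append((c.sample_id, age, H, S))
    pd.DataFrame(rows, columns=["sample_id", "age", "cumulative_hazard",
                                "survival"]).to_csv(path, sep=_sep(path),
                                                    index=False)


def read_curves(path):
    """Rebuild :class:`~coophaz.curves.IndividualCurves` from a long-format
    curve table."""
    from .curves import IndividualCurves
    df = pd.read_csv(path, sep=_sep(path))
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("age")
        haz = StepCurve(grp["age"].to_numpy(dtype=float),
                        grp["cumulative_hazard"].to_numpy(dtype=float),
                        "cumulative_hazard")
        surv = StepCurve(grp["age"].to_numpy(dtype=float),
                         grp["survival"].to_numpy(dtype=float), "survival")
        out.append(IndividualCurves(str(sid), haz, surv))
    return out


# ---------------------------------------------------------------------------
# flat key-value configuration files


def read_config_file(path) -> dict:
    """Parse a flat ``key = value`` text file (``#`` starts a comment).

    Keys may be namespaced as ``command.option`` to scope them to one CLI
    subcommand.  Values are returned as strings; the CLI coerces them.
    """
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise DataError(f"{path}:{lineno}: expected 'key = value'")
        key, value = stripped.split("=", 1)
        out[key.strip()] = value.strip()
    return out
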