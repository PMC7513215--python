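"""Readers and writers: delimited signal/feature matrices, EDF recordings,
and JSON + delimited classification reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .features import RawSignals
from .pipeline import ClassificationReport

__all__ = [
    "read_signal_matrix",
    "write_signal_matrix",
    "write_report",
    "read_report",
]


def _read_delimited(path: Path, rate: float | None) -> RawSignals:
    if rate is None:
        raise ConfigurationError("a sampling rate is required for delimited input")
    # header row detected by whether the first line parses as numbers
    first = pd.read_csv(path, sep=None, engine="python", header=None, nrows=1)
    has_header = not all(
        isinstance(v, (int, float, np.integer, np.floating)) for v in first.iloc[0]
    )
    frame = pd.read_csv(
        path, sep=None, engine="python", header=0 if has_header else None
    )
    if frame.isna().any().any():
        raise ConfigurationError(f"{path}: ragged rows or missing cells")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: non-numeric cell ({exc})") from exc
    names = [str(c) for c in frame.columns] if has_header else []
    return RawSignals(values=values, rate=rate, channel_names=names)


def _read_edf(path: Path) -> RawSignals:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ConfigurationError("EDF input needs the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return RawSignals(
        values=raw.get_data().T,
        rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def read_signal_matrix(
    path: str | Path, fmt: str = "auto", rate: float | None = None
) -> RawSignals:
    """Load a samples x channels matrix from delimited text or EDF.

    ``fmt='auto'`` dispatches on the ``.edf`` suffix; comma and tab
    delimiters are auto-detected for text input, which requires ``rate``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    if fmt not in {"auto", "delimited", "edf"}:
        raise ConfigurationError(f"unknown format {fmt!r}")
    if fmt == "edf" or (fmt == "auto" and path.suffix.lower() == ".edf"):
        return _read_edf(path)
    return _read_delimited(path, rate)


def write_signal_matrix(signals: RawSignals, path: str | Path) -> None:
    pd.DataFrame(signals.values, columns=signals.channel_names).to_csv(
        path, index=False
    )


def write_report(
    report: ClassificationReport | pd.DataFrame, path: str | Path
) -> None:
    """Write a report as JSON plus a delimited twin (same stem, .csv).

    Numeric fields are serialized at full precision; re-reading the JSON
    reproduces them exactly. A comparison table (DataFrame) keeps its config
    order.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    if isinstance(report, pd.DataFrame):
        path.write_text(json.dumps(report.to_dict(orient="records")))
        report.to_csv(csv_path, index=False)
        return
    path.write_text(json.dumps(report.to_dict()))
    rows = [
        {"fold": i + 1, "accuracy": acc, "n_components": k}
        for i, (acc, k) in enumerate(
            zip(report.fold_accuracies, report.n_components)
        )
    ]
    rows.append(
        {"fold": "mean", "accuracy": report.mean_accuracy, "n_components": ""}
    )
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_report(path: str | Path) -> ClassificationReport | pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, list):
        return pd.DataFrame(payload)
    return ClassificationReport(**payload)
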