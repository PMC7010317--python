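"""Report bundle assembly: CSV tables, run manifest, overlay index."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_report", "config_hash"]


def config_hash(config_obj) -> str:
    """Stable short hash of a (nested) configuration structure."""
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return {f: getattr(o, f) for f in o.__dataclass_fields__}
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"unhashable config element {type(o)}")

    payload = json.dumps(config_obj, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_report(
    out_dir,
    *,
    features: pd.DataFrame | None = None,
    contingency=None,
    p_matrix: pd.DataFrame | None = None,
    fa_results: dict | None = None,
    manifest: dict | None = None,
    overlays: list | None = None,
) -> dict:
    """Write the result bundle under ``out_dir`` with deterministic names.

    Emits (when the corresponding input is given) ``cell_features.csv``,
    ``group_frequencies.csv``, ``fisher_fdr_matrix.csv``,
    ``fa_comparisons.csv``, ``overlays.txt`` and always ``manifest.json``.
    Returns the mapping of logical name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    if features is not None:
        path = out / "cell_features.csv"
        features.to_csv(path, index=False)
        written["cell_features"] = str(path)
    if contingency is not None:
        path = out / "group_frequencies.csv"
        pd.DataFrame(
            {
                "group": contingency.groups,
                "blebbing": contingency.counts[:, 0],
                "non_blebbing": contingency.counts[:, 1],
                "frequency": contingency.frequencies,
            }
        ).to_csv(path, index=False)
        written["group_frequencies"] = str(path)
    if p_matrix is not None:
        path = out / "fisher_fdr_matrix.csv"
        p_matrix.to_csv(path)
        written["fisher_fdr_matrix"] = str(path)
    if fa_results is not None:
        rows = []
        for method in ("tukey", "rank"):
            for r in fa_results.get(method, []):
                rows.append(
                    {
                        "group_a": r.pair[0],
                        "group_b": r.pair[1],
                        "statistic": r.statistic,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                        "method": r.method,
                    }
                )
        path = out / "fa_comparisons.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written["fa_comparisons"] = str(path)
    if overlays:
        path = out / "overlays.txt"
        path.write_text("\n".join(str(p) for p in overlays) + "\n")
        written["overlays"] = str(path)

    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest or {}, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written["manifest"] = str(path)
    return written
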