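"""Best-effort loader for the publicly deposited curiosity/creativity panel.

The reanalyzed dataset (N = 400 employees, three occasions three months
apart; seven self-rated curiosity items, four supervisor-rated creativity
items) is deposited at the Open Science Framework under project ``d48xa``.
This module downloads the deposited files through the OSF v2 API and
builds composite scores (item means per occasion).  It is an optional
convenience: nothing else in the package depends on it, and it requires
network access.
"""

from __future__ import annotations

import json
import re
import urllib.request
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelDataset

OSF_PROJECT = "d48xa"
_API = "https://api.osf.io/v2/nodes/{node}/files/osfstorage/?page[size]=100"


def fetch_osf(out_dir, project: str = OSF_PROJECT, timeout: float = 10.0) -> list[Path]:
    """Download every file of the OSF project into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(_API.format(node=project), timeout=timeout) as fh:
        listing = json.load(fh)
    saved: list[Path] = []
    for item in listing.get("data", []):
        attrs = item.get("attributes", {})
        if attrs.get("kind") != "file":
            continue
        name = attrs["name"]
        url = item["links"]["download"]
        dest = out / name
        with urllib.request.urlopen(url, timeout=timeout) as src, open(dest, "wb") as dst:
            dst.write(src.read())
        saved.append(dest)
    if not saved:
        raise RuntimeError(f"no files found in OSF project {project}")
    return saved


def load_osf_panel(path, n_occasions: int = 3) -> PanelDataset:
    """Composite the deposited item-level table into a 3-wave panel.

    Expects a CSV/SPSS-export-style table with one row per person and
    item columns whose names carry the construct, occasion and item
    number (e.g. ``cu1_3`` or ``T1cur3``-style).  Composites are item
    means per occasion; curiosity maps to ``x``, creativity to ``y``.
    """
    path = Path(path)
    if path.suffix.lower() in (".sav",):
        raise ValueError("SPSS input not supported; export to CSV first")
    df = pd.read_csv(path)
    pat = re.compile(r"(?i)(cur|cu|creat|cr)[^0-9]*([1-3])[^0-9]*([0-9]+)")
    groups: dict[tuple[str, int], list[str]] = {}
    for col in df.columns:
        m = pat.search(col)
        if not m:
            continue
        construct = "x" if m.group(1).lower().startswith("cu") else "y"
        occ = int(m.group(2))
        groups.setdefault((construct, occ), []).append(col)
    if not groups:
        raise ValueError(f"could not identify item columns in {path.name}; "
                         "pass a pre-composited long CSV to PanelDataset.read_csv instead")
    rows = []
    for t in range(1, n_occasions + 1):
        sub = pd.DataFrame({"person_id": np.arange(1, len(df) + 1), "occasion": t})
        for construct in ("x", "y"):
            cols = groups.get((construct, t), [])
            sub[construct] = df[cols].mean(axis=1) if cols else np.nan
        rows.append(sub)
    long = pd.concat(rows, ignore_index=True)
    return PanelDataset(long[["person_id", "occasion", "x", "y"]])
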