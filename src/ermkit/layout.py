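"""Electrode layout: 10-10 labels, schematic scalp positions, cluster pooling.

The default layout covers the 62 scalp channels of an equidistant cap
(10-10 names, FCz reference excluded).  Positions are schematic 2-D head
coordinates (x: left negative / right positive, y: frontal positive /
occipital negative, unit head radius) used for topography interpolation.
Each hemisphere is divided into six electrode clusters:

    OC  occipital          P   parietal          PT  parieto-temporal
    CE  central            FR  frontal           AT  anterior-temporal

The membership table is a plain DataFrame and is meant to be edited or
replaced (``load_layout``/``save_layout`` round-trip it as TSV).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CLUSTERS",
    "default_layout",
    "load_layout",
    "save_layout",
    "posterior_channels",
    "frontal_channels",
    "central_channels",
]

CLUSTERS = ("OC", "P", "PT", "CE", "FR", "AT")

# rows front (positive y) to back; (label, x, y, cluster)
_DEFAULT = [
    ("Fp1", -0.20, 0.90, "FR"), ("Fpz", 0.00, 0.92, "FR"), ("Fp2", 0.20, 0.90, "FR"),
    ("AF7", -0.55, 0.75, "AT"), ("AF3", -0.25, 0.72, "FR"), ("AFz", 0.00, 0.72, "FR"),
    ("AF4", 0.25, 0.72, "FR"), ("AF8", 0.55, 0.75, "AT"),
    ("F9", -0.90, 0.55, "AT"), ("F7", -0.70, 0.52, "AT"), ("F5", -0.52, 0.52, "FR"),
    ("F3", -0.35, 0.52, "FR"), ("F1", -0.17, 0.52, "FR"), ("Fz", 0.00, 0.52, "FR"),
    ("F2", 0.17, 0.52, "FR"), ("F4", 0.35, 0.52, "FR"), ("F6", 0.52, 0.52, "FR"),
    ("F8", 0.70, 0.52, "AT"), ("F10", 0.90, 0.55, "AT"),
    ("FT7", -0.82, 0.28, "AT"), ("FC5", -0.60, 0.27, "AT"), ("FC3", -0.38, 0.26, "CE"),
    ("FC1", -0.18, 0.26, "CE"), ("FC2", 0.18, 0.26, "CE"), ("FC4", 0.38, 0.26, "CE"),
    ("FC6", 0.60, 0.27, "AT"), ("FT8", 0.82, 0.28, "AT"),
    ("T7", -0.92, 0.00, "AT"), ("C5", -0.68, 0.00, "CE"), ("C3", -0.45, 0.00, "CE"),
    ("C1", -0.22, 0.00, "CE"), ("Cz", 0.00, 0.00, "CE"), ("C2", 0.22, 0.00, "CE"),
    ("C4", 0.45, 0.00, "CE"), ("C6", 0.68, 0.00, "CE"), ("T8", 0.92, 0.00, "AT"),
    ("TP7", -0.82, -0.28, "PT"), ("CP5", -0.60, -0.27, "PT"), ("CP3", -0.38, -0.26, "CE"),
    ("CP1", -0.18, -0.26, "CE"), ("CPz", 0.00, -0.26, "CE"), ("CP2", 0.18, -0.26, "CE"),
    ("CP4", 0.38, -0.26, "CE"), ("CP6", 0.60, -0.27, "PT"), ("TP8", 0.82, -0.28, "PT"),
    ("P7", -0.70, -0.52, "PT"), ("P5", -0.52, -0.52, "P"), ("P3", -0.35, -0.52, "P"),
    ("P1", -0.17, -0.52, "P"), ("Pz", 0.00, -0.52, "P"), ("P2", 0.17, -0.52, "P"),
    ("P4", 0.35, -0.52, "P"), ("P6", 0.52, -0.52, "P"), ("P8", 0.70, -0.52, "PT"),
    ("PO7", -0.55, -0.75, "OC"), ("PO3", -0.25, -0.72, "OC"), ("POz", 0.00, -0.72, "OC"),
    ("PO4", 0.25, -0.72, "OC"), ("PO8", 0.55, -0.75, "OC"),
    ("O1", -0.20, -0.90, "OC"), ("Oz", 0.00, -0.92, "OC"), ("O2", 0.20, -0.90, "OC"),
]


def _hemisphere(label: str) -> str:
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:
        return "M"
    return "L" if int(digits) % 2 == 1 else "R"


def default_layout() -> pd.DataFrame:
    """The 62-channel default layout (label, x, y, hemisphere, cluster)."""
    df = pd.DataFrame(_DEFAULT, columns=["label", "x", "y", "cluster"])
    df["hemisphere"] = df["label"].map(_hemisphere)
    return df[["label", "x", "y", "hemisphere", "cluster"]]


def load_layout(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "x", "y", "hemisphere", "cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"layout file missing columns: {sorted(missing)}")
    if df["label"].duplicated().any():
        raise ValueError("layout labels must be unique")
    unknown = set(df["cluster"]) - set(CLUSTERS)
    if unknown:
        raise ValueError(f"unknown clusters in layout: {sorted(unknown)}")
    return df[["label", "x", "y", "hemisphere", "cluster"]]


def save_layout(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def posterior_channels(layout: pd.DataFrame) -> list[str]:
    """Channels in the occipital/parietal/parieto-temporal clusters."""
    return layout.loc[layout["cluster"].isin(["OC", "P", "PT"]), "label"].tolist()


def frontal_channels(layout: pd.DataFrame) -> list[str]:
    """Channels in the frontal/anterior-temporal clusters."""
    return layout.loc[layout["cluster"].isin(["FR", "AT"]), "label"].tolist()


def central_channels(layout: pd.DataFrame) -> list[str]:
    return layout.loc[layout["cluster"] == "CE", "label"].tolist()
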