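"""Plain-text table readers/writers for the pipeline's TSV interfaces."""

from __future__ import annotations

import pandas as pd

from .speciation import MEASUREMENT_COLUMNS, SpeciationError


def read_measurements(path: str) -> pd.DataFrame:
    """Read a tidy measurement TSV and validate its schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SpeciationError(f"{path}: missing measurement columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts(path: str) -> pd.DataFrame:
    """Taxa x samples counts TSV; first column is the taxon id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_taxonomy(path: str) -> pd.DataFrame:
    """Taxonomy TSV: taxon id, phylum, family, phylotype."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("phylum", "family", "phylotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: taxonomy table lacks column {col!r}")
    return df.fillna("unclassified")


def read_similarity(path: str) -> pd.DataFrame:
    """Square phylotype similarity matrix TSV with matching row/col labels."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design(path: str) -> pd.DataFrame:
    """Sample design TSV: sample, arm (treatment|control), time_h."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "arm", "time_h"):
        if col not in df.columns:
            raise ValueError(f"{path}: design table lacks column {col!r}")
    return df.set_index("sample")
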