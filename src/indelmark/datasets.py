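"""Packaged reference tables from the published tomato InDel marker study.

Three small TSV fixtures ship with the package: the per-chromosome InDel
counts of the genome-wide catalogue, the allele numbers and PIC values of the
63 core markers, and the 24-digit DNA fingerprints of the 52 germplasm
accessions together with the 24-marker core panel order.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_indel_counts",
    "load_marker_pic",
    "load_fingerprints",
    "load_core_panel",
    "fingerprints_to_matrix",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("indelmark.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def load_indel_counts() -> pd.DataFrame:
    """Per-chromosome insertion/deletion counts of the genome-wide InDel
    catalogue (columns Chromosome, Insertion, Deletion, Total, InDel_pct)."""
    return _read("table1_indel_counts.tsv")


def load_marker_pic() -> pd.DataFrame:
    """Allele number and PIC of the 63 core InDel markers
    (columns Chromosome, Marker, AlleleNumber, PIC)."""
    return _read("table2_marker_pic.tsv")


def load_fingerprints() -> pd.Series:
    """Published 24-digit fingerprints of the 52 accessions, as a Series
    indexed by accession id (published row order preserved)."""
    df = _read("table3_fingerprints.tsv", dtype={"Fingerprint": str})
    return df.set_index("Accession")["Fingerprint"]


def load_core_panel() -> pd.DataFrame:
    """The published 24-marker core fingerprinting panel in digit order
    (columns Order, Marker, Chromosome)."""
    return _read("core_panel.tsv")


def fingerprints_to_matrix(
    fingerprints: pd.Series | None = None, panel: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Expand fingerprint strings into a band-code genotype matrix
    (accessions x panel markers)."""
    fingerprints = load_fingerprints() if fingerprints is None else fingerprints
    panel = load_core_panel() if panel is None else panel
    markers = list(panel["Marker"])
    rows = {
        acc: [int(c) for c in code] for acc, code in fingerprints.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=markers).astype(int)
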