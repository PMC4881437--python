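"""Packaged reference tables.

``load_candidate_table`` returns the published 42-gene candidate table (gene symbol,
Entrez id, CNA direction, % overlap with normal-population CNVs, and the
univariate Cox OS/DFS coefficients with p-values from the 1820-tumor
expression meta-cohort), transcribed from the printed table. The loader
verifies a checksum so silent edits of the fixture are caught.

``load_roster`` returns the expression meta-cohort roster: per GEO series,
the tumor and normal sample counts that make up the 1820-tumor / 167-normal
meta-cohort.
"""

from __future__ import annotations

import hashlib
import importlib.resources

import pandas as pd

_CHECKSUMS = {
    "candidate_gene_table.tsv": "4a43323e8b40d2bdbd96634fd6eab87af0b69516fbf114c7a2d9ea2ba89dafde",
    "meta_cohort_roster.tsv": "47a0fc470762b6e3de9b920c082874e1b6dfe1254e355388de58092880dd1461",
}


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("crcmet.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_candidate_table() -> pd.DataFrame:
    """The 42-gene candidate table as typed records (one row per gene)."""
    df = _load("candidate_gene_table.tsv")
    if len(df) != 42:
        raise ValueError(f"expected 42 candidate records, found {len(df)}")
    return df


def load_roster() -> pd.DataFrame:
    """Per-dataset tumor/normal sample counts of the expression meta-cohort."""
    return _load("meta_cohort_roster.tsv")
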