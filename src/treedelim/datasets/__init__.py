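"""Bundled reference tables for desk-scale validation.

Published per-haplogroup delimitation statistics for 17 New World deer
cytochrome-b haplogroups — one table computed on a maximum-likelihood tree
(bootstrap support), one on a Bayesian tree (posterior support) — and the
matching grouped genetic-distance matrix (percent units; diagonal = mean
within-group p-distance, lower triangle = between-group p, upper = K2P; NA
diagonal entries mark singleton haplogroups).
"""

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_ml_delimitation",
    "load_bi_delimitation",
    "load_grouped_distances",
]

_NUMERIC = [
    "intra", "inter", "ratio",
    "pid_strict_mean", "pid_strict_low", "pid_strict_high",
    "pid_liberal_mean", "pid_liberal_low", "pid_liberal_high",
    "av_mrca_tips",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files(__package__) / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"], **kwargs)


def _delimitation(name: str) -> pd.DataFrame:
    frame = _read(name, dtype={"support": str})
    for col in _NUMERIC:
        frame[col] = pd.to_numeric(frame[col])
    return frame


def load_ml_delimitation() -> pd.DataFrame:
    """Delimitation statistics on the maximum-likelihood tree (17 rows)."""
    return _delimitation("deer_ml_delimitation.tsv")


def load_bi_delimitation() -> pd.DataFrame:
    """Delimitation statistics on the Bayesian tree (17 rows)."""
    return _delimitation("deer_bi_delimitation.tsv")


def load_grouped_distances() -> pd.DataFrame:
    """17x17 grouped distance matrix in percent (p lower, K2P upper)."""
    frame = _read("deer_grouped_distances.tsv", index_col=0)
    return frame.astype(np.float64)
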