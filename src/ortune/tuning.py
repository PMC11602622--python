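"""Tuning-breadth and response-spectrum analysis.

A receptor's *response spectrum* is its vector of mean response amplitudes
r_i over a panel of n stimuli.  Tuning breadth is quantified by lifetime
sparseness (Rolls–Tovée):

    S = (1 − (Σ r_i / n)² / Σ (r_i² / n)) / (1 − 1/n)

bounded in [0, 1]: S = 0 for a uniform responder, S = 1 for a receptor
responding to exactly one stimulus.  The formula is undefined for negative
amplitudes, so negative entries are clamped to 0 first (and counted).

Spectra can be min–max normalized against designated reference stimuli
(strongest ligand = 100%, solvent = 0%), and receptor similarity is
summarized by agglomerative clustering of normalized spectra (Euclidean
distance, UPGMA/average linkage by default; both recorded in the result).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ResponseSpectrum",
    "SparsenessResult",
    "DendrogramResult",
    "sparseness",
    "mean_spectra",
    "normalize_spectrum",
    "cluster_receptors",
]


@dataclass
class ResponseSpectrum:
    """Per-stimulus mean response amplitudes of one receptor."""

    receptor: str
    responses: pd.Series  # index = stimulus labels, values in %

    def __post_init__(self) -> None:
        self.responses = pd.Series(self.responses, dtype=float)
        if self.responses.size < 2:
            raise ValueError("a response spectrum needs at least 2 stimuli")
        if self.responses.index.duplicated().any():
            raise ValueError("stimulus labels must be unique")


@dataclass
class SparsenessResult:
    value: float  # S in [0, 1]
    n: int  # stimuli used
    n_clamped: int  # negative responses set to 0


@dataclass
class DendrogramResult:
    """Agglomerative merge tree over receptors."""

    linkage: np.ndarray  # scipy linkage matrix; heights non-decreasing
    labels: list[str]
    metric: str
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment from the top n_clusters − 1 merges."""
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return rec(tree, tree.dist) + ";"


def sparseness(spectrum: ResponseSpectrum | pd.Series | np.ndarray) -> SparsenessResult:
    """Lifetime sparseness of a response spectrum, with negative clamping.

    Negative amplitudes are set to 0 before evaluating the formula (they
    are outside its domain); the number clamped is reported.  An all-zero
    spectrum after clamping has no defined tuning breadth and raises.
    """
    if isinstance(spectrum, ResponseSpectrum):
        r = spectrum.responses.to_numpy(dtype=float)
    else:
        r = np.asarray(pd.Series(spectrum, dtype=float))
    n = r.size
    if n < 2:
        raise ValueError("sparseness needs at least 2 stimuli")
    if not np.all(np.isfinite(r)):
        raise ValueError("spectrum contains non-finite values")
    n_clamped = int((r < 0).sum())
    r = np.where(r < 0, 0.0, r)
    sum_sq = np.sum(r**2) / n
    if sum_sq == 0:
        raise ValueError("all responses are zero after clamping; sparseness undefined")
    ratio = (np.sum(r) / n) ** 2 / sum_sq
    s = (1.0 - ratio) / (1.0 - 1.0 / n)
    return SparsenessResult(value=float(s), n=n, n_clamped=n_clamped)


def mean_spectra(
    panel: pd.DataFrame,
    include_stimuli: list[str] | None = None,
    exclude_stimuli: list[str] | None = None,
) -> pd.DataFrame:
    """Across-animal mean response spectra from a long-format panel.

    ``panel`` has columns (animal, receptor, stimulus, amplitude).  By
    default every stimulus in the panel (controls included) enters the
    spectrum; ``exclude_stimuli`` drops e.g. controls for sensitivity
    analyses.
    """
    df = panel
    if include_stimuli is not None:
        df = df[df["stimulus"].isin(include_stimuli)]
    if exclude_stimuli is not None:
        df = df[~df["stimulus"].isin(exclude_stimuli)]
    wide = df.pivot_table(index="receptor", columns="stimulus", values="amplitude", aggfunc="mean")
    return wide.reindex(columns=pd.unique(df["stimulus"]))


def normalize_spectrum(
    spectrum: pd.Series,
    reference_max_stimulus: str = "9-ODA",
    reference_min_stimulus: str = "solvent",
    clip: bool = False,
) -> tuple[pd.Series, pd.Series]:
    """Min–max normalize a spectrum to [0, 100]% between reference stimuli.

    x' = 100·(x − min_ref)/(max_ref − min_ref), with the strongest-ligand
    response (9-ODA by default) as 100% and the solvent response as 0%.
    Returns (normalized spectrum, boolean flags for values outside
    [0, 100]); with ``clip=True`` flagged values are clipped into range.
    """
    s = pd.Series(spectrum, dtype=float)
    for ref in (reference_max_stimulus, reference_min_stimulus):
        if ref not in s.index:
            raise ValueError(f"reference stimulus {ref!r} not in spectrum")
    hi = s[reference_max_stimulus]
    lo = s[reference_min_stimulus]
    if hi <= lo:
        raise ValueError(
            f"reference max ({hi:g}) must exceed reference min ({lo:g})"
        )
    out = 100.0 * (s - lo) / (hi - lo)
    flags = (out < 0) | (out > 100)
    if clip:
        out = out.clip(0.0, 100.0)
    return out, flags


def cluster_receptors(
    spectra: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> DendrogramResult:
    """Agglomerative clustering of receptor response spectra.

    Rows are receptors, columns stimuli (identical stimulus sets required;
    any NaN marks a receptor missing a stimulus).  Defaults: Euclidean
    distance with average (UPGMA) linkage, recorded in the result.
    """
    if spectra.shape[0] < 2:
        raise ValueError("need at least 2 receptors to cluster")
    if spectra.isna().any().any():
        raise ValueError("spectra have mismatched stimulus sets (NaN entries)")
    dists = pdist(spectra.to_numpy(dtype=float), metric=metric)
    linkage = hierarchy.linkage(dists, method=method)
    return DendrogramResult(
        linkage=linkage,
        labels=[str(i) for i in spectra.index],
        metric=metric,
        method=method,
    )
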