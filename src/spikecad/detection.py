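"""Scikit-learn style front end to multi-timescale assembly detection."""

from __future__ import annotations

from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .agglomeration import AssemblyCatalog, DetectionConfig, detect_assemblies
from .io import SpikeDataset, dataset_from_frame

__all__ = ["AssemblyDetector"]


def _coerce_dataset(X) -> SpikeDataset:
    if isinstance(X, SpikeDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return dataset_from_frame(X)
    if isinstance(X, dict):
        tmax = max((float(np.max(v)) for v in X.values() if len(v)), default=1.0)
        return SpikeDataset(units={u: np.sort(np.asarray(v, float))
                                   for u, v in X.items()},
                            span=(0.0, tmax if tmax > 0 else 1.0))
    if isinstance(X, (list, tuple)):
        return _coerce_dataset({i: v for i, v in enumerate(X)})
    raise TypeError(
        "X must be a SpikeDataset, a (unit_id, time_s) DataFrame, a dict of "
        "spike-time arrays, or a list of spike-time arrays")


class AssemblyDetector(BaseEstimator):
    """Detect cell assemblies across multiple temporal scales.

    Bins the multivariate spike data at every width in ``bin_widths``, tests
    all unit pairs for lagged dependence with the non-stationarity-corrected
    F statistic, and recursively agglomerates significant pairs into
    higher-order assemblies under strict Bonferroni budgeting.  Clusters of
    units (with lag constellations) are exposed sklearn-style after
    :meth:`fit`.

    Parameters
    ----------
    bin_widths : sequence of float
        Strictly increasing bin widths Δ in seconds.
    l_max : int
        Maximum lag tested, in bins; the lag range is ``-l_max..l_max``.
    alpha : float
        Family-wise significance level before Bonferroni correction.
    reference_policy : {"mirror", "fixed"}
        Reference lag for the difference statistic: the time-reversed lag
        (with ``sync_reference`` for synchrony), or ``-(l_max + 1)`` fixed.
    sync_reference : int
        Reference lag used when the selected lag is 0 (default -2).
    segment_length : int
        Segment length (bins) for the local variance estimate.
    dof_policy : {"auto", "full", "conservative"}
        Denominator degrees of freedom of the F test.
    mean_gate : float
        Minimum expected joint count for a pair to be testable.
    apply_floor : bool
        Subtract non-informative floor counts at coarse bin widths.
    min_rate : float or None
        If set, exclude units firing below this rate (Hz) before testing.
    prune_cosine : float or None
        Optional across-scale pruning threshold on membership cosine
        distance (presentation aid, off by default).
    prune_across_scale_subsets : bool
        Optionally remove assemblies that are unit-subsets of larger ones
        regardless of scale.

    Attributes
    ----------
    catalog_ : AssemblyCatalog
        All detected assemblies with lag vectors, p-values and
        characteristic scales.
    assemblies_ : list of Assembly
        Shortcut to ``catalog_.assemblies``.
    labels_ : ndarray of shape (n_units,)
        Per-unit assembly label: index (into ``assemblies_``) of the
        lowest-p assembly containing the unit, or -1 for unassigned units.
    unit_ids_ : list
        Unit identifiers in the order used by ``labels_``.

    Examples
    --------
    >>> from spikecad.synthetic import generate_scenario
    >>> ds, truth = generate_scenario("figure1", seed=1)
    >>> det = AssemblyDetector(bin_widths=(0.015, 0.1), l_max=10)
    >>> det.fit(ds)                                   # doctest: +SKIP
    """

    def __init__(self, bin_widths: Sequence[float] = (0.015, 0.05, 0.1, 0.15, 1.0),
                 l_max: int = 10, alpha: float = 0.05,
                 reference_policy: str = "mirror", sync_reference: int = -2,
                 segment_length: int = 100, dof_policy: str = "auto",
                 mean_gate: float = 4.0, apply_floor: bool = True,
                 min_rate: float | None = None,
                 prune_cosine: float | None = None,
                 prune_across_scale_subsets: bool = False):
        self.bin_widths = bin_widths
        self.l_max = l_max
        self.alpha = alpha
        self.reference_policy = reference_policy
        self.sync_reference = sync_reference
        self.segment_length = segment_length
        self.dof_policy = dof_policy
        self.mean_gate = mean_gate
        self.apply_floor = apply_floor
        self.min_rate = min_rate
        self.prune_cosine = prune_cosine
        self.prune_across_scale_subsets = prune_across_scale_subsets

    def _config(self) -> DetectionConfig:
        return DetectionConfig(
            deltas=tuple(self.bin_widths), l_max=self.l_max, alpha=self.alpha,
            reference_policy=self.reference_policy,
            sync_reference=self.sync_reference,
            segment_length=self.segment_length, dof_policy=self.dof_policy,
            mean_gate=self.mean_gate, apply_floor=self.apply_floor,
            min_rate=self.min_rate, prune_cosine=self.prune_cosine,
            prune_across_scale_subsets=self.prune_across_scale_subsets)

    def fit(self, X, y=None) -> "AssemblyDetector":
        """Run detection on multivariate spike-time data."""
        dataset = _coerce_dataset(X)
        config = self._config()   # validates parameters
        if dataset.n_units < 2:
            raise ValueError("need at least two units")
        self.catalog_: AssemblyCatalog = detect_assemblies(dataset,
                                                           config=config)
        self.assemblies_ = self.catalog_.assemblies
        self.unit_ids_ = list(self.catalog_.unit_ids)
        self.n_units_ = len(self.unit_ids_)
        by_p = sorted(range(len(self.assemblies_)),
                      key=lambda i: self.assemblies_[i].p_value)
        labels = {}
        for i in reversed(by_p):
            for u in self.assemblies_[i].units:
                labels[u] = i
        self.labels_ = np.array([labels.get(u, -1) for u in self.unit_ids_])
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the per-unit assembly labels."""
        return self.fit(X).labels_
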