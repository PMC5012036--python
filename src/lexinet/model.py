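"""Model / results interface for hybridization-network inference.

The :class:`HybridizationNetworkModel` is built from data (a distance
matrix, a presence-absence matrix, or a raw cognate database) together
with the detection parameters; :meth:`~HybridizationNetworkModel.fit`
runs the agglomeration and returns a
:class:`HybridizationNetworkResults` carrying the tree, the reticulation
estimates with their fit diagnostics, and a text ``summary()``.
"""

from __future__ import annotations

from typing import Optional

from . import export
from .cognate_io import CognateDatabase, PresenceAbsenceMatrix, build_presence_absence
from .distances import DistanceMatrix, hamming_distance, read_phylip
from .hybrid_detection import (
    DetectionParameters,
    HybridizationNetwork,
    default_parameters,
    infer_network,
    iterate_removal,
)

__all__ = ["HybridizationNetworkModel", "HybridizationNetworkResults"]


class HybridizationNetworkModel:
    """Distance-based inference of an explicit hybridization network.

    Parameters
    ----------
    distance_matrix
        Symmetric matrix of evolutionary distances over the taxa.
    min_score, alpha_min, alpha_max
        Detection thresholds; any left as ``None`` falls back to the
        size-dependent defaults (permissive for up to 20 taxa,
        restrictive above).

    Examples
    --------
    >>> from lexinet import HybridizationNetworkModel, worked_example_database
    >>> model = HybridizationNetworkModel.from_database(worked_example_database())
    >>> res = model.fit()
    >>> res.n_reticulations
    1
    """

    def __init__(
        self,
        distance_matrix: DistanceMatrix,
        min_score: Optional[float] = None,
        alpha_min: Optional[float] = None,
        alpha_max: Optional[float] = None,
    ):
        self.distance_matrix = distance_matrix
        base = default_parameters(distance_matrix.n)
        self.params = DetectionParameters(
            min_score=base.min_score if min_score is None else min_score,
            alpha_min=base.alpha_min if alpha_min is None else alpha_min,
            alpha_max=base.alpha_max if alpha_max is None else alpha_max,
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_presence_absence(
        cls,
        pam: PresenceAbsenceMatrix,
        strategy: str = "missing_as_zero",
        **detection,
    ) -> "HybridizationNetworkModel":
        return cls(hamming_distance(pam, strategy=strategy), **detection)

    @classmethod
    def from_database(
        cls, db: CognateDatabase, strategy: str = "missing_as_zero", **detection
    ) -> "HybridizationNetworkModel":
        return cls.from_presence_absence(
            build_presence_absence(db), strategy=strategy, **detection
        )

    @classmethod
    def from_phylip(cls, path, **detection) -> "HybridizationNetworkModel":
        return cls(read_phylip(path), **detection)

    # ------------------------------------------------------------------
    def fit(
        self, iterate: bool = False, max_rounds: int = 5
    ) -> "HybridizationNetworkResults":
        """Run the agglomeration; optionally re-run on pruned matrices."""
        if iterate:
            net = iterate_removal(self.distance_matrix, self.params, max_rounds)
        else:
            net = infer_network(self.distance_matrix, self.params)
        return HybridizationNetworkResults(self, net)


class HybridizationNetworkResults:
    """Estimates and diagnostics of a fitted hybridization network.

    Attributes
    ----------
    network : HybridizationNetwork
        Tree skeleton plus reticulation records.
    reticulations : pandas.DataFrame
        One row per event: recipient, donors with their member taxa, the
        degrees (summing to 1), the reticulation score, and the
        agglomeration step and round of detection.
    """

    def __init__(self, model: HybridizationNetworkModel, network: HybridizationNetwork):
        self.model = model
        self.network = network

    @property
    def tree(self):
        return self.network.tree

    @property
    def newick(self) -> str:
        return self.network.tree.newick()

    @property
    def n_reticulations(self) -> int:
        return self.network.n_reticulations

    @property
    def reticulations(self):
        return export.reticulations_frame(self.network)

    def to_enewick(self) -> str:
        return export.to_enewick(self.network)

    def write_reticulations_tsv(self, path) -> None:
        export.write_reticulations_tsv(self.network, path)

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        p = self.model.params
        n = self.model.distance_matrix.n
        lines = [
            "Hybridization network (distance-based NJ agglomeration)",
            "=" * 60,
            f"Taxa:                 {n}",
            f"min_score:            {p.min_score:g}",
            f"alpha range:          [{p.alpha_min:g}, {p.alpha_max:g}]",
            f"Reticulations:        {self.n_reticulations}",
        ]
        if self.network.reticulations:
            lines.append("-" * 60)
            lines.append(
                f"{'recipient':<12}{'donor1':<10}{'deg1':>7}"
                f"  {'donor2':<10}{'deg2':>7}{'score':>9}{'LS':>10}"
            )
            for r in self.network.reticulations:
                lines.append(
                    f"{r.recipient:<12}{r.donor1:<10}{r.degree1:>7.3f}"
                    f"  {r.donor2:<10}{r.degree2:>7.3f}{r.score:>9.3f}{r.ls:>10.3g}"
                )
        lines.append("=" * 60)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<HybridizationNetworkResults: {self.n_reticulations} reticulation(s), "
            f"{self.model.distance_matrix.n} taxa>"
        )
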