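"""Parcellated time-series container and state/input partition.

A recording is a ``p x (T+1)`` matrix: one row per cortical parcel, one
column per scan, columns indexed ``k = 0..T`` at a fixed sampling interval
``dt`` (the scanner repetition time, 0.72 s for the reference acquisition).
A :class:`PartitionSpec` splits the ``p`` parcels into ``m`` dynamical
states and ``n`` exogenous inputs, ``m + n = p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParcellatedTimeSeries", "PartitionSpec"]


@dataclass
class ParcellatedTimeSeries:
    """Region-by-time activity matrix with sampling metadata.

    Parameters
    ----------
    values
        Real array of shape ``(p, T+1)``; column ``k`` is the activity of
        every parcel at scan ``k``. Arbitrary (BOLD-like) units.
    dt
        Sampling interval in seconds; must be positive.
    parcel_labels
        ``p`` unique parcel names, in row order.
    """

    values: np.ndarray
    dt: float
    parcel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x time matrix")
        p, cols = self.values.shape
        if p < 2:
            raise ValueError(f"need at least 2 parcels, got {p}")
        if cols < 2:
            raise ValueError(f"need at least 2 time points (T >= 1), got {cols}")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite entries")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.parcel_labels:
            self.parcel_labels = [f"parcel_{i:03d}" for i in range(p)]
        if len(self.parcel_labels) != p:
            raise ValueError(
                f"{len(self.parcel_labels)} labels for {p} parcels"
            )
        if len(set(self.parcel_labels)) != p:
            raise ValueError("parcel labels must be unique")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        """Number of transitions (columns are k = 0..T)."""
        return self.values.shape[1] - 1

    def downsample(self, factor: int) -> "ParcellatedTimeSeries":
        """Keep every ``factor``-th scan, multiplying ``dt`` accordingly.

        Keeping every 2nd column of a 0.72 s series yields a 1.44 s series,
        the protocol used to probe sampling-interval sensitivity.
        """
        if factor < 1 or int(factor) != factor:
            raise ValueError(f"downsample factor must be a positive integer, got {factor}")
        factor = int(factor)
        return ParcellatedTimeSeries(
            values=self.values[:, ::factor].copy(),
            dt=self.dt * factor,
            parcel_labels=list(self.parcel_labels),
        )


@dataclass
class PartitionSpec:
    """Ordered split of parcels into ``m`` states and ``n`` inputs.

    The state parcels carry the dynamics ``x(k)``; the input parcels act as
    exogenous drives ``u(k)``. Indices refer to rows of the time-series
    matrix and must be disjoint; ``n = 0`` (fully autonomous) is allowed.
    """

    state_idx: list[int]
    input_idx: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.state_idx = [int(i) for i in self.state_idx]
        self.input_idx = [int(i) for i in self.input_idx]
        if len(self.state_idx) < 1:
            raise ValueError("need at least one state parcel")
        overlap = set(self.state_idx) & set(self.input_idx)
        if overlap:
            raise ValueError(f"state/input indices overlap: {sorted(overlap)}")
        if len(set(self.state_idx)) != len(self.state_idx):
            raise ValueError("duplicate state indices")
        if len(set(self.input_idx)) != len(self.input_idx):
            raise ValueError("duplicate input indices")

    @property
    def m(self) -> int:
        return len(self.state_idx)

    @property
    def n(self) -> int:
        return len(self.input_idx)

    def validate_for(self, ts: ParcellatedTimeSeries) -> None:
        """Check the partition addresses exactly the parcels of ``ts``."""
        if self.m + self.n != ts.p:
            raise ValueError(
                f"partition covers {self.m + self.n} parcels, series has {ts.p}"
            )
        all_idx = set(self.state_idx) | set(self.input_idx)
        if all_idx != set(range(ts.p)):
            missing = sorted(set(range(ts.p)) - all_idx)
            raise ValueError(f"partition does not cover parcels {missing}")

    def split(self, ts: ParcellatedTimeSeries) -> tuple[np.ndarray, np.ndarray]:
        """Return the state block ``X`` (m x T+1) and input block ``U`` (n x T+1)."""
        self.validate_for(ts)
        X = ts.values[self.state_idx, :]
        U = ts.values[self.input_idx, :]
        return X, U

    @classmethod
    def from_labels(
        cls,
        ts: ParcellatedTimeSeries,
        state_labels: list[str],
        input_labels: list[str],
    ) -> "PartitionSpec":
        pos = {lab: i for i, lab in enumerate(ts.parcel_labels)}
        for lab in list(state_labels) + list(input_labels):
            if lab not in pos:
                raise KeyError(f"partition label {lab!r} not found in time series")
        return cls(
            state_idx=[pos[lab] for lab in state_labels],
            input_idx=[pos[lab] for lab in input_labels],
        )
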