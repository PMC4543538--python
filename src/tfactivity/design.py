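"""Experimental design description for the two-color time-course layout.

The reference layout is a CO-releasing-molecule (CORM-3 / iCORM-3) exposure
time course: a pre-treatment sample at t = 0 min and five post-treatment
samples, hybridised against an untreated control with four replicates per
condition (two biological repeats, each with a technical dye-swap repeat).
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_TIME_POINTS_MIN = (0, 10, 20, 40, 60, 120)


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling times and replicate structure of a two-color time course.

    Parameters
    ----------
    time_points_min : tuple of float
        Ordered sampling times in minutes. The first entry is the
        pre-treatment reference time.
    n_bio : int
        Number of biological repeats per condition.
    n_dye_swap : int
        Number of technical dye-swap repeats per biological repeat.
    conditions : tuple of str
        Condition labels.
    """

    time_points_min: tuple = DEFAULT_TIME_POINTS_MIN
    n_bio: int = 2
    n_dye_swap: int = 2
    conditions: tuple = ("CORM-3",)

    def __post_init__(self):
        tp = tuple(float(t) for t in self.time_points_min)
        if len(tp) < 1:
            raise ValueError("at least one time point is required")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must be strictly increasing")
        if self.n_bio < 1 or self.n_dye_swap < 1:
            raise ValueError("replicate counts must be positive")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition label is required")
        object.__setattr__(self, "time_points_min", tp)
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def n_time(self) -> int:
        return len(self.time_points_min)

    @property
    def n_replicates(self) -> int:
        """Total replicates per condition (biological x dye-swap)."""
        return self.n_bio * self.n_dye_swap

    @property
    def replicate_ids(self) -> list:
        """Replicate labels, e.g. ``bio1.fwd`` / ``bio1.swap``.

        Even dye-swap indices carry the experimental sample in Cy5
        (``fwd``); odd indices are the swapped labelling (``swap``).
        """
        ids = []
        for b in range(self.n_bio):
            for s in range(self.n_dye_swap):
                tag = "fwd" if s % 2 == 0 else "swap"
                suffix = "" if self.n_dye_swap <= 2 else str(s // 2 + 1)
                ids.append(f"bio{b + 1}.{tag}{suffix}")
        return ids

    def experimental_dye(self, replicate_index: int) -> str:
        """Dye carrying the experimental (treated) sample for a replicate."""
        return "Cy5" if (replicate_index % self.n_dye_swap) % 2 == 0 else "Cy3"

    def to_dict(self) -> dict:
        return {
            "time_points_min": list(self.time_points_min),
            "n_bio": self.n_bio,
            "n_dye_swap": self.n_dye_swap,
            "conditions": list(self.conditions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            time_points_min=tuple(d["time_points_min"]),
            n_bio=int(d["n_bio"]),
            n_dye_swap=int(d["n_dye_swap"]),
            conditions=tuple(d["conditions"]),
        )
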