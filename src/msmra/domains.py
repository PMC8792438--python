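"""Two-partition multi-source grouping for transfer scenarios.

Recordings (subject-session units) are grouped in pairs to form source
domains: pairing balances fidelity of each domain's marginal
distribution against the number of per-domain model branches.  Two
protocols are supported:

* ``cross_subject`` — within one session, hold out one subject as the
  unlabeled target and pair the remaining subjects (14 subjects give
  N = 7 source domains).
* ``cross_session`` — within one subject, the first two sessions form a
  single source domain (N = 1) and the final session is the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import IncompleteGridError, OverlapError, UnpairableError
from .preprocess import FeatureTensor

__all__ = ["SourceDomain", "DomainPartition", "pair_sources", "leave_one_out_splits"]


@dataclass
class SourceDomain:
    """One source domain: a pair of recordings with a pooled view."""

    index: int
    members: list[FeatureTensor]

    @property
    def pooled_values(self) -> np.ndarray:
        return np.vstack([m.values for m in self.members])

    @property
    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([m.labels for m in self.members])

    @property
    def n_windows(self) -> int:
        return sum(m.n_windows for m in self.members)


@dataclass
class DomainPartition:
    """N source domains plus one target recording.

    Target labels are retained for evaluation only; training treats the
    target as unlabeled.
    """

    sources: list[SourceDomain]
    target: FeatureTensor
    scenario: str = "cross_subject"

    @property
    def n_domains(self) -> int:
        return len(self.sources)

    @property
    def split_id(self) -> str:
        s, sess = self.target.subject_id, self.target.session_id
        return f"{self.scenario}:target={s or '?'}/{sess or '?'}"

    def manifest(self) -> dict:
        """JSON-serialisable description sufficient to rebuild the split."""
        return {
            "scenario": self.scenario,
            "sources": [
                {"index": d.index, "members": [list(m.key) for m in d.members]}
                for d in self.sources
            ],
            "target": list(self.target.key),
        }


def pair_sources(
    recordings: list[FeatureTensor],
    target: FeatureTensor,
    scenario: str = "cross_subject",
    pairing_order: list[int] | None = None,
    allow_singleton: bool = False,
) -> DomainPartition:
    """Group source recordings in consecutive pairs.

    ``pairing_order`` permutes the recordings before pairing (defaults
    to the given order).  ``cross_session`` expects exactly two
    recordings, which become a single source domain.
    """
    for r in recordings:
        if r is target or (r.key != ("", "") and r.key == target.key):
            raise OverlapError(f"target recording {target.key} also listed as a source")
    if scenario not in ("cross_subject", "cross_session"):
        raise ValueError(f"unknown scenario {scenario!r}")

    if pairing_order is not None:
        recordings = [recordings[i] for i in pairing_order]

    if scenario == "cross_session":
        if len(recordings) != 2:
            raise UnpairableError(
                f"cross_session expects the two earlier sessions, got {len(recordings)}"
            )
        sources = [SourceDomain(index=0, members=list(recordings))]
        return DomainPartition(sources=sources, target=target, scenario=scenario)

    if len(recordings) % 2 != 0:
        if not allow_singleton:
            leftover = recordings[-1].key
            raise UnpairableError(
                f"odd number of source recordings ({len(recordings)}); "
                f"leftover {leftover} (pass allow_singleton=True to keep it)"
            )
    sources = []
    i = 0
    while i < len(recordings):
        members = recordings[i : i + 2]
        sources.append(SourceDomain(index=len(sources), members=list(members)))
        i += 2
    return DomainPartition(sources=sources, target=target, scenario="cross_subject")


def leave_one_out_splits(
    grid: dict[tuple[str, str], FeatureTensor],
    scenario: str = "cross_subject",
    pairing_seed: int | None = None,
) -> list[DomainPartition]:
    """All leave-one-out partitions over a complete subject x session grid.

    ``grid`` maps ``(subject_id, session_id)`` to its feature tensor.
    ``cross_subject`` yields one partition per (session, held-out
    subject); ``cross_session`` yields one per subject, with the last
    session (by sorted id) as target and the previous two as one source
    domain.  ``pairing_seed`` optionally shuffles the pairing order for
    sensitivity checks; the default is ascending subject id.
    """
    subjects = sorted({k[0] for k in grid})
    sessions = sorted({k[1] for k in grid})
    missing = [(su, se) for su in subjects for se in sessions if (su, se) not in grid]
    if missing:
        raise IncompleteGridError(f"missing grid cells: {missing[:5]}")

    splits: list[DomainPartition] = []
    if scenario == "cross_subject":
        for se in sessions:
            for held in subjects:
                rest = [grid[(su, se)] for su in subjects if su != held]
                order = None
                if pairing_seed is not None:
                    rng = np.random.default_rng(pairing_seed)
                    order = list(rng.permutation(len(rest)))
                splits.append(
                    pair_sources(rest, grid[(held, se)], "cross_subject", pairing_order=order)
                )
    elif scenario == "cross_session":
        if len(sessions) < 3:
            raise IncompleteGridError(
                f"cross_session needs >= 3 sessions, got {len(sessions)}"
            )
        first_two, last = sessions[:2], sessions[-1]
        for su in subjects:
            splits.append(
                pair_sources(
                    [grid[(su, se)] for se in first_two],
                    grid[(su, last)],
                    "cross_session",
                )
            )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return splits
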