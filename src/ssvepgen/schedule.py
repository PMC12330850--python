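"""Trial schedules for the generalization paradigm.

The design presents eight Gabor orientations (CS+ = +45 deg; the opposite
-45 deg and six graded neighbours as generalization stimuli) flickering at
7.5 Hz for 4 s each, separated by 2-3 s ISIs.  The acquisition phase presents
18 trials per orientation; the context phase repeats the same timing inside
six aversive and six neutral picture blocks of 24 cues each, again yielding
18 trials per orientation and context.  The CS+ is reinforced on 100% of
trials, and trial order is pseudo-randomized so that no more than three
identical orientations occur consecutively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ORIENTATIONS = (-45, 15, 25, 35, 45, 55, 65, 75)
CS_PLUS = 45
CUE_DURATION_S = 4.0
ISI_RANGE_S = (2.0, 3.0)
LEAD_IN_RANGE_S = (5.0, 7.0)
TRIALS_PER_BLOCK = 24
N_PER_CELL = 18

_COLUMNS = [
    "phase",
    "block_index",
    "context",
    "orientation_deg",
    "onset_s",
    "duration_s",
    "isi_s",
    "reinforced",
]


class ScheduleConstraintError(RuntimeError):
    """Raised when no run-length-valid trial order is found."""


@dataclass
class TrialSchedule:
    """Ordered trial records of one experimental phase.

    ``records`` is a DataFrame with columns phase, block_index, context,
    orientation_deg, onset_s (relative to block start), duration_s, isi_s
    (gap following the cue) and reinforced.
    """

    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    @property
    def phase(self) -> str:
        return self.records["phase"].iloc[0]

    def cell_counts(self) -> pd.Series:
        """Trial counts per (orientation, context) cell."""
        return self.records.groupby(["orientation_deg", "context"]).size()

    def longest_run(self) -> int:
        """Length of the longest run of identical orientations, by scan."""
        ori = self.records["orientation_deg"].to_numpy()
        best = run = 1
        for a, b in zip(ori[1:], ori[:-1]):
            run = run + 1 if a == b else 1
            best = max(best, run)
        return best

    def block_durations(self) -> pd.Series:
        """Implied duration of each block: lead-in + cues + inner ISIs."""
        out = {}
        for (ctx, blk), grp in self.records.groupby(["context", "block_index"]):
            lead_in = grp["onset_s"].iloc[0]
            dur = lead_in + grp["duration_s"].sum() + grp["isi_s"].iloc[:-1].sum()
            out[(ctx, blk)] = dur
        return pd.Series(out)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrialSchedule":
        df = pd.read_csv(path, sep="\t")
        df["reinforced"] = df["reinforced"].astype(bool)
        return cls(df[_COLUMNS])


def _runs_ok(seq, max_run=3):
    run = 1
    for a, b in zip(seq[1:], seq[:-1]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return False
    return True


def _block_timing(rng, n_trials):
    lead_in = rng.uniform(*LEAD_IN_RANGE_S)
    isis = rng.uniform(*ISI_RANGE_S, size=n_trials)
    onsets = lead_in + np.concatenate(
        [[0.0], np.cumsum(CUE_DURATION_S + isis[:-1])]
    )
    return onsets, isis


def generate_schedule(
    phase: str,
    seed: int,
    n_per_cell: int = N_PER_CELL,
    max_attempts: int = 1000,
) -> TrialSchedule:
    """Generate a pseudo-randomized trial schedule for one phase.

    Parameters
    ----------
    phase : {"acquisition", "context"}
        Acquisition presents each orientation ``n_per_cell`` times with no
        background context; the context phase presents ``n_per_cell`` trials
        per orientation inside each of the aversive and neutral block sets.
    seed : int
        Seeds all randomization (trial order, ISIs, lead-ins, block order).
    n_per_cell : int
        Trials per orientation (and context) cell; must fill 24-trial blocks
        evenly in the context phase (multiple of 3).

    Raises
    ------
    ScheduleConstraintError
        If no order satisfying the run-length constraint is found within
        ``max_attempts`` resampling attempts.
    """
    if phase not in ("acquisition", "context"):
        raise ValueError(f"unknown phase {phase!r}")
    rng = np.random.default_rng(seed)

    if phase == "acquisition":
        # one continuous sequence; a single block for timing purposes
        base = np.repeat(ORIENTATIONS, n_per_cell)
        blocks = None
        for _ in range(max_attempts):
            seq = rng.permutation(base)
            if _runs_ok(seq):
                blocks = [("none", 0, seq)]
                break
    else:
        n_total = n_per_cell * len(ORIENTATIONS)
        if n_total % TRIALS_PER_BLOCK:
            raise ValueError(
                f"n_per_cell={n_per_cell} does not fill {TRIALS_PER_BLOCK}-"
                "trial blocks evenly"
            )
        n_blocks = n_total // TRIALS_PER_BLOCK
        per_block = np.repeat(ORIENTATIONS, TRIALS_PER_BLOCK // len(ORIENTATIONS))
        labels = [("aversive", b) for b in range(n_blocks)] + [
            ("neutral", b) for b in range(n_blocks)
        ]
        blocks = None
        for _ in range(max_attempts):
            order = [labels[i] for i in rng.permutation(len(labels))]
            cand = [(ctx, blk, rng.permutation(per_block)) for ctx, blk in order]
            # run-length constraint holds over the full presentation order,
            # including across block boundaries
            if _runs_ok(np.concatenate([seq for _, _, seq in cand])):
                blocks = cand
                break

    if blocks is None:
        raise ScheduleConstraintError(
            f"no orientation order satisfying the run-length constraint "
            f"found in {max_attempts} attempts"
        )

    rows = []
    for ctx, blk, seq in blocks:
        onsets, isis = _block_timing(rng, len(seq))
        for ori, onset, isi in zip(seq, onsets, isis):
            rows.append(
                (phase, blk, ctx, int(ori), onset, CUE_DURATION_S, isi,
                 ori == CS_PLUS)
            )

    df = pd.DataFrame(rows, columns=_COLUMNS)
    return TrialSchedule(df)
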