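"""Continuous recognition task (CRT) sequencing.

A CRT presents each picture as New, immediately repeats it (Rep1..Rep3,
half the pictures a fourth time, Rep4), and re-presents it once more
after 9-15 intervening items (the N-back trial, affording recognition).
Pictures shown only once (Catch) are interleaved to break the rhythm.
The final pictures of the task are not re-presented, so with the default
parameters (72 pictures, 22 catches, two blocks) the generated counts
are 72 New, 72 each Rep1-Rep3, 36 Rep4, 66 N-back and 22 Catch trials.

The generator is a randomized greedy scheduler with retry: it emits
picture runs, eligible N-backs and catch insertions trial by trial,
forcing an N-back out before its lag window closes.  A delayed
recognition list (repeated + catch + novel pictures, shuffled) can be
derived from any generated sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRIAL_TYPES = ("New", "Rep1", "Rep2", "Rep3", "Rep4", "NBack", "Catch")

__all__ = [
    "TaskSequence",
    "SequencingError",
    "generate_crt",
    "validate_sequence",
    "generate_delayed_list",
]


class SequencingError(ValueError):
    """Raised when a sequence with the requested constraints cannot be built."""


@dataclass
class TaskSequence:
    """An ordered CRT trial list.

    Attributes
    ----------
    trials : list of (picture_id, trial_type, block)
        trial_type is one of ``TRIAL_TYPES``; block is 1-based.
    lag_record : dict
        picture_id -> number of intervening items between the picture's
        last consecutive repetition and its N-back re-appearance.
    """

    trials: list[tuple[int, str, int]]
    lag_record: dict[int, int] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        """Number of trials of each type."""
        out = {t: 0 for t in TRIAL_TYPES}
        for _, ttype, _ in self.trials:
            out[ttype] += 1
        return out

    def picture_ids(self, include_catch: bool = True) -> list[int]:
        seen: list[int] = []
        for pid, ttype, _ in self.trials:
            if ttype == "Catch" and not include_catch:
                continue
            if pid not in seen:
                seen.append(pid)
        return seen

    def to_table(self):
        """Sequence as a pandas DataFrame (trial_index, picture_id, trial_type, block)."""
        import pandas as pd

        return pd.DataFrame(
            [(i, pid, t, b) for i, (pid, t, b) in enumerate(self.trials)],
            columns=["trial_index", "picture_id", "trial_type", "block"],
        )


def _emit_block(
    rng: np.random.Generator,
    pics: list[int],
    rep4_flags: dict[int, bool],
    n_unrepeated: int,
    n_catch: int,
    catch_ids: list[int],
    lag_range: tuple[int, int],
    block: int,
) -> tuple[list[tuple[int, str, int]], dict[int, int]] | None:
    """One greedy attempt at a block. Returns None on dead end."""
    lag_min, lag_max = lag_range
    order = list(pics)
    rng.shuffle(order)
    no_nback = set(order[len(order) - n_unrepeated:]) if n_unrepeated > 0 else set()

    trials: list[tuple[int, str, int]] = []
    lags: dict[int, int] = {}
    pending: list[tuple[int, int]] = []  # (pid, index of last run trial)
    ptr = 0
    catches_left = n_catch

    def run_len(pid: int) -> int:
        return 5 if rep4_flags[pid] else 4

    def emit_run(pid: int) -> None:
        labels = ["New", "Rep1", "Rep2", "Rep3"] + (["Rep4"] if rep4_flags[pid] else [])
        for lab in labels:
            trials.append((pid, lab, block))
        if pid not in no_nback:
            pending.append((pid, len(trials) - 1))

    def lag_now(end_idx: int) -> int:
        # intervening items if the N-back were emitted as the next trial
        return len(trials) - end_idx - 1

    while ptr < len(order) or pending or catches_left > 0:
        # forced N-backs whose window closes this trial
        at_limit = [i for i, (_, e) in enumerate(pending) if lag_now(e) >= lag_max]
        if len(at_limit) > 1:
            return None  # two windows close simultaneously
        if at_limit:
            pid, e = pending.pop(at_limit[0])
            lag = lag_now(e)
            if not (lag_min <= lag <= lag_max):
                return None
            trials.append((pid, "NBack", block))
            lags[pid] = lag
            continue

        options: list[tuple[str, int, float]] = []
        max_pending_lag = max((lag_now(e) for _, e in pending), default=-1)
        if ptr < len(order):
            nxt = order[ptr]
            if max_pending_lag + run_len(nxt) <= lag_max:
                options.append(("run", ptr, 2.0))
        for i, (_, e) in enumerate(pending):
            lag = lag_now(e)
            if lag >= lag_min:
                urgency = 1.0 + 3.0 * (lag - lag_min) / max(lag_max - lag_min, 1)
                options.append(("nback", i, urgency))
        last_type = trials[-1][1] if trials else None
        catch_ok = catches_left > 0 and last_type in ("Rep3", "Rep4", "NBack")
        if catch_ok:
            remaining_slots = (len(order) - ptr) + len(pending)
            if catches_left >= remaining_slots + 1 or not options:
                # must place now (slots running out) or nothing else can move
                options = [("catch", 0, 1.0)]
            else:
                w = 0.8 * catches_left / max(remaining_slots, 1)
                options.append(("catch", 0, w))

        if not options:
            return None  # dead end: everything pending is below lag_min

        weights = np.array([w for _, _, w in options])
        kind, arg, _ = options[rng.choice(len(options), p=weights / weights.sum())]
        if kind == "run":
            emit_run(order[ptr])
            ptr += 1
        elif kind == "nback":
            pid, e = pending.pop(arg)
            lag = lag_now(e)
            trials.append((pid, "NBack", block))
            lags[pid] = lag
        else:
            cid = catch_ids[n_catch - catches_left]
            trials.append((cid, "Catch", block))
            catches_left -= 1

    return trials, lags


def generate_crt(
    n_pictures: int = 72,
    rep4_fraction: float = 0.5,
    lag_range: tuple[int, int] = (9, 15),
    n_catch: int = 22,
    n_blocks: int = 2,
    seed: int = 0,
    n_unrepeated: int = 6,
    max_attempts: int = 500,
) -> TaskSequence:
    """Generate a CRT trial sequence.

    Parameters
    ----------
    n_pictures : int
        Pictures presented as New and immediately repeated.
    rep4_fraction : float
        Fraction of pictures repeated a fourth consecutive time.
    lag_range : (int, int)
        Allowed number of intervening items between a picture's last
        consecutive repetition and its N-back re-appearance.
    n_catch : int
        Pictures presented exactly once, inserted only after Rep3, Rep4
        or N-back trials.
    n_blocks : int
        Sequential blocks with disjoint picture sets.
    n_unrepeated : int
        Pictures at the end of the task that get no N-back trial
        (the last ones introduced in the final block).

    Returns
    -------
    TaskSequence

    Raises
    ------
    SequencingError
        If no valid ordering exists under the lag constraints.
    """
    if n_pictures < 1:
        raise SequencingError("n_pictures must be >= 1")
    if lag_range[0] < 1 or lag_range[1] < lag_range[0]:
        raise SequencingError(f"infeasible lag_range {lag_range}: need 1 <= min <= max")
    if not 0.0 <= rep4_fraction <= 1.0:
        raise SequencingError("rep4_fraction must be in [0, 1]")
    n_blocks = min(n_blocks, n_pictures)

    rng = np.random.default_rng(seed)

    # disjoint picture sets per block, as equal as possible
    pics_all = list(range(1, n_pictures + 1))
    rng.shuffle(pics_all)
    base, extra = divmod(n_pictures, n_blocks)
    block_pics: list[list[int]] = []
    start = 0
    for b in range(n_blocks):
        size = base + (1 if b < extra else 0)
        block_pics.append(sorted(pics_all[start:start + size]))
        start += size

    # Rep4 assignment balanced per block
    n_rep4_total = int(round(rep4_fraction * n_pictures))
    rep4_flags: dict[int, bool] = {p: False for p in pics_all}
    assigned = 0
    for b, pics in enumerate(block_pics):
        quota = int(round(rep4_fraction * len(pics)))
        quota = min(quota, n_rep4_total - assigned, len(pics))
        if b == n_blocks - 1:
            quota = min(n_rep4_total - assigned, len(pics))
        for p in rng.choice(pics, size=quota, replace=False):
            rep4_flags[int(p)] = True
        assigned += quota

    # catch ids and per-block counts
    catch_ids_all = list(range(n_pictures + 1, n_pictures + n_catch + 1))
    cbase, cextra = divmod(n_catch, n_blocks)
    catch_counts = [cbase + (1 if b < cextra else 0) for b in range(n_blocks)]

    # the unrepeated pictures close each block: their runs supply the
    # intervening items the last N-backs of the block need
    ubase, uextra = divmod(n_unrepeated, n_blocks)
    unrep_counts = [ubase + (1 if b >= n_blocks - uextra else 0) for b in range(n_blocks)]

    trials: list[tuple[int, str, int]] = []
    lag_record: dict[int, int] = {}
    cstart = 0
    for b in range(n_blocks):
        pics = block_pics[b]
        n_unrep = min(unrep_counts[b], len(pics))
        # a picture whose N-back cannot fit (too few later items) is unrepeated
        later_items = sum(
            4 + int(rep4_flags[p]) for bb in range(b, n_blocks) for p in block_pics[bb]
        )
        if later_items - (4 + 1) < lag_range[0] and n_unrep < len(pics):
            n_unrep = len(pics)
        cids = catch_ids_all[cstart:cstart + catch_counts[b]]
        cstart += catch_counts[b]
        block_trials = None
        for _ in range(max_attempts):
            sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
            block_trials = _emit_block(
                sub, pics, rep4_flags, n_unrep, len(cids), cids, lag_range, b + 1
            )
            if block_trials is not None:
                break
        if block_trials is None:
            raise SequencingError(
                f"could not schedule block {b + 1}: lag constraints {lag_range} "
                f"infeasible for {len(pics)} pictures with {len(cids)} catches"
            )
        trials.extend(block_trials[0])
        lag_record.update(block_trials[1])

    return TaskSequence(trials=trials, lag_record=lag_record)


def validate_sequence(
    seq: TaskSequence, lag_range: tuple[int, int] = (9, 15)
) -> list[str]:
    """Check every sequence invariant; return a list of violation messages.

    An empty list means the sequence is valid.  Checked invariants:
    each non-catch picture appears as New exactly once with Rep1..Rep3
    immediately consecutive (Rep4, if present, immediately after Rep3);
    every N-back lag lies within ``lag_range``; no N-back precedes its
    Rep3; catch pictures appear exactly once and only after Rep3, Rep4
    or N-back trials.
    """
    report: list[str] = []
    lag_min, lag_max = lag_range
    by_pic: dict[int, list[tuple[int, str]]] = {}
    for i, (pid, ttype, _) in enumerate(seq.trials):
        by_pic.setdefault(pid, []).append((i, ttype))

    for pid, occ in by_pic.items():
        types = [t for _, t in occ]
        if types == ["Catch"]:
            i = occ[0][0]
            if i == 0 or seq.trials[i - 1][1] not in ("Rep3", "Rep4", "NBack"):
                report.append(f"picture {pid}: catch trial not after Rep3/Rep4/NBack")
            continue
        if "Catch" in types:
            report.append(f"picture {pid}: mixes catch and non-catch trials")
            continue
        if types.count("New") != 1:
            report.append(f"picture {pid}: appears as New {types.count('New')} times")
            continue
        run = ["New", "Rep1", "Rep2", "Rep3"]
        if types[:4] != run:
            report.append(f"picture {pid}: run is {types[:4]}, expected {run}")
            continue
        idxs = [i for i, _ in occ]
        run_end = 3
        if len(types) > 4 and types[4] == "Rep4":
            run_end = 4
        if idxs[:run_end + 1] != list(range(idxs[0], idxs[0] + run_end + 1)):
            report.append(f"picture {pid}: repetitions not immediately consecutive")
        rest = types[run_end + 1:]
        if rest not in ([], ["NBack"]):
            report.append(f"picture {pid}: unexpected trailing trials {rest}")
            continue
        if rest == ["NBack"]:
            lag = idxs[run_end + 1] - idxs[run_end] - 1
            if not (lag_min <= lag <= lag_max):
                report.append(
                    f"picture {pid}: N-back lag {lag} outside [{lag_min}, {lag_max}]"
                )
            rec = seq.lag_record.get(pid)
            if rec is not None and rec != lag:
                report.append(f"picture {pid}: recorded lag {rec} != actual {lag}")
    return report


def generate_delayed_list(
    seq: TaskSequence,
    n_repeated: int = 60,
    n_novel: int = 30,
    seed: int = 0,
) -> list[tuple[int, str]]:
    """Build the delayed recognition list from a CRT sequence.

    Contains ``n_repeated`` pictures sampled from those repeated in the
    CRT, every catch picture, and ``n_novel`` novel ids absent from the
    sequence, in a seed-shuffled order.
    """
    rng = np.random.default_rng(seed)
    repeated = [
        pid for pid, occ in _group(seq).items() if any(t != "Catch" for _, t in occ)
    ]
    catch = [pid for pid, occ in _group(seq).items() if [t for _, t in occ] == ["Catch"]]
    if n_repeated > len(repeated):
        raise SequencingError(
            f"n_repeated={n_repeated} exceeds {len(repeated)} repeated pictures"
        )
    chosen = [int(p) for p in rng.choice(repeated, size=n_repeated, replace=False)]
    max_id = max((pid for pid, _, _ in seq.trials), default=0)
    novel = list(range(max_id + 1, max_id + 1 + n_novel))
    items = (
        [(p, "repeated") for p in chosen]
        + [(p, "catch") for p in catch]
        + [(p, "novel") for p in novel]
    )
    order = rng.permutation(len(items))
    return [items[i] for i in order]


def _group(seq: TaskSequence) -> dict[int, list[tuple[int, str]]]:
    by_pic: dict[int, list[tuple[int, str]]] = {}
    for i, (pid, ttype, _) in enumerate(seq.trials):
        by_pic.setdefault(pid, []).append((i, ttype))
    return by_pic
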