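"""SPADE — Sequential PAttern Discovery using Equivalence classes.

A from-scratch vertical-format frequent-sequence miner.  The database maps
each patient to a time-ordered list of itemsets (the events of one day).
Every pattern node carries an id-list of (patient, time) pairs recording
*all* times at which an embedding of the pattern can end; candidate
patterns are grown depth-first by

* S-extension: append a new single-item element occurring strictly later
  than some embedding of the prefix, and
* I-extension: add an item (lexicographically after the current last
  element's items) to the last element at the same time.

Support is the number of distinct patients containing the pattern, counted
once per patient regardless of repeat occurrences; a pattern is frequent
when support >= ceil(minsup * n).  Anti-monotonicity (every prefix of a
frequent pattern is frequent, at no smaller support) is what makes the
depth-first pruning exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

__all__ = [
    "SequenceDatabase",
    "SequentialPattern",
    "from_patient_sequences",
    "to_vertical",
    "enumerate_frequent",
    "pattern_contains",
    "stratify_pattern_support",
    "mine_per_cluster",
    "pattern_string",
    "patterns_to_dot",
]

# sid -> [(time, frozenset of tokens)], times strictly increasing
SequenceDatabase = dict[str, list[tuple[int, frozenset]]]

Pattern = tuple[tuple[str, ...], ...]  # ordered elements; each element sorted


@dataclass
class SequentialPattern:
    elements: Pattern
    support: int
    support_frac: float
    outcome_split: tuple[int, int] | None = None  # (n with PPD, n without)

    def __str__(self) -> str:
        return pattern_string(self.elements)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.elements)


def pattern_string(elements: Pattern) -> str:
    return " → ".join("+".join(e) for e in elements)


def from_patient_sequences(sequences) -> SequenceDatabase:
    """Group each patient's (token, day) stream into per-day itemsets."""
    db: SequenceDatabase = {}
    for pid, seq in sequences.items():
        by_day: dict[int, set] = {}
        for tok, t in zip(seq.tokens, seq.times):
            by_day.setdefault(int(t), set()).add(tok)
        db[str(pid)] = [(t, frozenset(by_day[t])) for t in sorted(by_day)]
    return db


def _validate(db: SequenceDatabase) -> None:
    for sid, seq in db.items():
        times = [t for t, _ in seq]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"times must strictly increase within patient {sid!r}")
        if any(not s for _, s in seq):
            raise ValueError(f"empty itemset in patient {sid!r}")


def to_vertical(db: SequenceDatabase) -> dict[str, dict[str, list[int]]]:
    """Vertical index: item -> {patient -> sorted occurrence times}."""
    _validate(db)
    vert: dict[str, dict[str, list[int]]] = {}
    for sid in sorted(db):
        for t, itemset in db[sid]:
            for item in itemset:
                vert.setdefault(item, {}).setdefault(sid, []).append(t)
    return vert


def item_supports(db: SequenceDatabase) -> dict[str, int]:
    return {item: len(occ) for item, occ in to_vertical(db).items()}


def enumerate_frequent(
    db: SequenceDatabase,
    minsup: float,
    max_len: int = 5,
    use_istep: bool = True,
) -> list[SequentialPattern]:
    """All sequential patterns with distinct-patient support >= ceil(minsup*n)
    and at most ``max_len`` items, each with its exact support.

    Output is sorted by support (descending) then pattern lexicographically,
    so reports are reproducible regardless of patient ordering.
    """
    if not (0.0 < minsup <= 1.0):
        raise ValueError("minsup must lie in (0, 1]")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = len(db)
    if n == 0:
        return []
    minsup_count = ceil(minsup * n)
    vert = to_vertical(db)
    freq_items = sorted(item for item, occ in vert.items() if len(occ) >= minsup_count)
    out: list[SequentialPattern] = []

    def emit(pattern: Pattern, idlist: dict[str, list[int]]) -> None:
        out.append(SequentialPattern(pattern, len(idlist), len(idlist) / n))

    def extend(pattern: Pattern, idlist: dict[str, list[int]], length: int) -> None:
        if length >= max_len:
            return
        last = pattern[-1]
        for x in freq_items:
            # S-step: x strictly after the earliest embedding end
            s_idlist: dict[str, list[int]] = {}
            for sid, ends in idlist.items():
                occ = vert[x].get(sid)
                if not occ:
                    continue
                first_end = ends[0]
                later = [t for t in occ if t > first_end]
                if later:
                    s_idlist[sid] = later
            if len(s_idlist) >= minsup_count:
                pat = pattern + ((x,),)
                emit(pat, s_idlist)
                extend(pat, s_idlist, length + 1)
            # I-step: grow the last element, keeping items sorted to visit
            # each itemset exactly once
            if use_istep and x > last[-1]:
                i_idlist = {}
                for sid, ends in idlist.items():
                    occ = vert[x].get(sid)
                    if not occ:
                        continue
                    occ_set = set(occ)
                    both = [t for t in ends if t in occ_set]
                    if both:
                        i_idlist[sid] = both
                if len(i_idlist) >= minsup_count:
                    pat = pattern[:-1] + (last + (x,),)
                    emit(pat, i_idlist)
                    extend(pat, i_idlist, length + 1)

    for item in freq_items:
        idlist = {sid: list(occ) for sid, occ in vert[item].items()}
        pat: Pattern = ((item,),)
        emit(pat, idlist)
        extend(pat, idlist, 1)

    out.sort(key=lambda p: (-p.support, p.elements))
    return out


def pattern_contains(elements: Pattern, seq: list[tuple[int, frozenset]]) -> bool:
    """Greedy earliest-match containment test of a pattern in one patient's
    itemset sequence (used by the outcome stratifier and test oracles)."""
    pos = 0
    for element in elements:
        need = set(element)
        while pos < len(seq) and not need <= seq[pos][1]:
            pos += 1
        if pos >= len(seq):
            return False
        pos += 1
    return True


def supporting_patients(elements: Pattern, db: SequenceDatabase) -> set[str]:
    return {sid for sid, seq in db.items() if pattern_contains(elements, seq)}


def stratify_pattern_support(
    pattern: SequentialPattern | Pattern,
    db: SequenceDatabase,
    ppd_labels: dict[str, bool],
) -> tuple[int, int]:
    """(n supporters with PPD, n without); the two counts sum to the
    pattern's support."""
    elements = pattern.elements if isinstance(pattern, SequentialPattern) else pattern
    supp = supporting_patients(elements, db)
    missing = [sid for sid in supp if sid not in ppd_labels]
    if missing:
        raise ValueError(f"missing PPD label for supporting patients: {sorted(missing)[:5]}")
    pos = sum(1 for sid in supp if ppd_labels[sid])
    return pos, len(supp) - pos


def mine_per_cluster(
    db: SequenceDatabase,
    cluster_labels: dict[str, int],
    minsup: float = 0.10,
    max_len: int = 5,
    ppd_labels: dict[str, bool] | None = None,
    use_istep: bool = True,
) -> dict[int, list[SequentialPattern]]:
    """Run the miner within each cluster's sub-database; when PPD labels are
    supplied every pattern gets its outcome split (the green/grey pathway
    counts of the care-pathway diagrams)."""
    missing = [sid for sid in db if sid not in cluster_labels]
    if missing:
        raise ValueError(f"cluster label missing for patients: {sorted(missing)[:5]}")
    results: dict[int, list[SequentialPattern]] = {}
    for cl in sorted(set(cluster_labels.values())):
        sub = {sid: seq for sid, seq in db.items() if cluster_labels[sid] == cl}
        if not sub:
            results[cl] = []
            continue
        pats = enumerate_frequent(sub, minsup=minsup, max_len=max_len, use_istep=use_istep)
        if ppd_labels is not None:
            for p in pats:
                p.outcome_split = stratify_pattern_support(p, sub, ppd_labels)
        results[cl] = pats
    return results


def patterns_to_dot(patterns: list[SequentialPattern], title: str = "patterns") -> str:
    """DOT graph of single-item pattern chains; edges supporting PPD cases
    are drawn green, mirroring pathway-diagram conventions."""
    lines = [f'digraph "{title}" {{', "  rankdir=LR;"]
    for idx, p in enumerate(patterns):
        nodes = ["+".join(e) for e in p.elements]
        color = "darkgreen" if p.outcome_split and p.outcome_split[0] > 0 else "gray40"
        for a, b in zip(nodes, nodes[1:]):
            lines.append(f'  "{a}" -> "{b}" [color={color}, label="{p.support}"];')
        if len(nodes) == 1:
            lines.append(f'  "{nodes[0]}" [color={color}];')
        if idx > 200:
            break
    lines.append("}")
    return "\n".join(lines)
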