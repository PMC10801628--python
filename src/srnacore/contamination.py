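"""Environmental-contamination and minimum-length read filtering.

No-template (environment) control libraries capture reagent and lab
contamination.  A sample read is discarded when its sequence is identical
to an environmental read sequence or contains one as a contiguous
substring (forward orientation).  Matching is exact; indexed environment
sequences shorter than the minimum read length are excluded so that
trivially short patterns cannot delete everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import ReadRecord

DEFAULT_MIN_LENGTH = 15


def length_filter(
    reads: Sequence[ReadRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Partition reads into (kept, removed_short) at the minimum length."""
    kept, removed = [], []
    for r in reads:
        (kept if len(r.sequence) >= min_length else removed).append(r)
    return kept, removed


@dataclass
class EnvironmentIndex:
    """Deduplicated environment sequences with substring-query support.

    Queries are answered by length-stratified exact hashing: for each
    distinct indexed length L, every length-L substring of the query is
    looked up in a hash set.  With read lengths ≤ ~50 nt this is a few
    hundred O(1) probes per query and exactly reproduces a naive scan.
    """

    sequences: frozenset[str]
    min_length: int = DEFAULT_MIN_LENGTH
    n_too_short: int = 0
    _lengths: tuple[int, ...] = field(init=False, repr=False)
    _by_length: dict[int, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_length: dict[int, set[str]] = {}
        for seq in self.sequences:
            by_length.setdefault(len(seq), set()).add(seq)
        self._by_length = by_length
        self._lengths = tuple(sorted(by_length))

    def __len__(self) -> int:
        return len(self.sequences)

    def contains_match(self, query: str) -> bool:
        """True iff some indexed sequence is a substring of (or equals) query."""
        qlen = len(query)
        for L in self._lengths:
            if L > qlen:
                break
            bucket = self._by_length[L]
            for i in range(qlen - L + 1):
                if query[i : i + L] in bucket:
                    return True
        return False


def build_environment_index(
    env_reads: Iterable[ReadRecord | str],
    min_length: int = DEFAULT_MIN_LENGTH,
) -> EnvironmentIndex:
    """Index distinct environment read sequences of at least ``min_length``."""
    seqs: set[str] = set()
    n_short = 0
    for r in env_reads:
        seq = r.sequence if isinstance(r, ReadRecord) else r
        if len(seq) < min_length:
            n_short += 1
            continue
        seqs.add(seq)
    return EnvironmentIndex(frozenset(seqs), min_length, n_short)


def filter_environment(
    sample_reads: Sequence[ReadRecord],
    index: EnvironmentIndex,
    contain_both: bool = False,
) -> tuple[list[ReadRecord], list[ReadRecord], dict]:
    """Remove sample reads matching the environment index.

    A read is removed iff its sequence equals an indexed sequence or
    contains one as a contiguous substring.  With ``contain_both`` the
    symmetric case (sample read contained inside an environment sequence)
    is removed as well.  Returns (kept, removed, stats); stats reports the
    removed fraction per sample.
    """
    kept: list[ReadRecord] = []
    removed: list[ReadRecord] = []
    if len(index) == 0:
        stats = _stats(sample_reads, [])
        return list(sample_reads), [], stats
    contained_in_env: set[str] | None = None
    if contain_both:
        contained_in_env = set()
        distinct = {r.sequence for r in sample_reads}
        for env_seq in index.sequences:
            for seq in distinct:
                if len(seq) <= len(env_seq) and seq in env_seq:
                    contained_in_env.add(seq)
    for r in sample_reads:
        hit = index.contains_match(r.sequence)
        if not hit and contained_in_env is not None:
            hit = r.sequence in contained_in_env
        (removed if hit else kept).append(r)
    return kept, removed, _stats(sample_reads, removed)


def _stats(sample_reads: Sequence[ReadRecord], removed: Sequence[ReadRecord]) -> dict:
    per_sample_in: dict[str, int] = {}
    per_sample_removed: dict[str, int] = {}
    for r in sample_reads:
        per_sample_in[r.sample_id] = per_sample_in.get(r.sample_id, 0) + 1
    for r in removed:
        per_sample_removed[r.sample_id] = per_sample_removed.get(r.sample_id, 0) + 1
    fractions = {
        s: per_sample_removed.get(s, 0) / n if n else 0.0
        for s, n in per_sample_in.items()
    }
    return {
        "n_input": len(sample_reads),
        "n_removed": len(removed),
        "removed_fraction_per_sample": fractions,
    }
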