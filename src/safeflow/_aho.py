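"""Aho-Corasick multi-pattern matching over integer sequences.

Patterns and texts are sequences of edge-ids (arbitrary hashable symbols),
so substring containment between safe paths can be decided in time linear in
the total pattern/text length instead of quadratically.
"""

from __future__ import annotations

from collections import deque
from typing import Hashable, Iterable, Sequence


class AhoCorasick:
    """Classic trie + failure-link automaton; dict transitions per node."""

    def __init__(self, patterns: Iterable[Sequence[Hashable]]):
        self._goto: list[dict] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[int]] = [[]]
        self.patterns: list[tuple] = []
        for pid, pat in enumerate(patterns):
            self.patterns.append(tuple(pat))
            self._insert(pat, pid)
        self._build_failure_links()

    def _insert(self, pattern: Sequence[Hashable], pid: int) -> None:
        node = 0
        for sym in pattern:
            nxt = self._goto[node].get(sym)
            if nxt is None:
                nxt = len(self._goto)
                self._goto.append({})
                self._fail.append(0)
                self._out.append([])
                self._goto[node][sym] = nxt
            node = nxt
        self._out[node].append(pid)

    def _build_failure_links(self) -> None:
        queue = deque()
        for child in self._goto[0].values():
            self._fail[child] = 0
            queue.append(child)
        while queue:
            node = queue.popleft()
            for sym, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and sym not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(sym, 0)
                if self._fail[child] == child:  # root self-loop guard
                    self._fail[child] = 0
                self._out[child].extend(self._out[self._fail[child]])

    def iter_matches(self, text: Sequence[Hashable]):
        """Yield (end_index, pattern_id) for every occurrence in ``text``."""
        node = 0
        for i, sym in enumerate(text):
            while node and sym not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(sym, 0)
            for pid in self._out[node]:
                yield i, pid
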