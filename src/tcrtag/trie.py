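"""Aho-Corasick multi-keyword automaton.

The annotator classifies reads by locating short germline-identifying tags
inside each read.  Searching for all tags simultaneously is done with an
Aho-Corasick keyword trie: a trie over the keyword set augmented with
failure links, flattened here into a deterministic transition table so that
scanning a target is a single left-to-right pass, linear in the target
length plus the number of matches, independent of the number of keywords.
"""

from __future__ import annotations

from collections import deque
from typing import Iterator, Sequence


class DuplicateKeywordError(ValueError):
    """Raised when the same keyword is inserted twice."""


class AhoCorasick:
    """Prebuilt automaton over a fixed set of keywords.

    Parameters
    ----------
    keywords:
        Non-empty strings; must be pairwise distinct.

    Notes
    -----
    Matches are reported as ``(keyword_index, start_position)`` for every
    occurrence, including overlapping ones and keywords that are substrings
    of other keywords.
    """

    __slots__ = ("keywords", "_delta", "_out")

    def __init__(self, keywords: Sequence[str]) -> None:
        keywords = list(keywords)
        if len(set(keywords)) != len(keywords):
            dupes = sorted({k for k in keywords if keywords.count(k) > 1})
            raise DuplicateKeywordError(f"duplicate keywords: {dupes}")
        if any(not k for k in keywords):
            raise ValueError("empty keyword not allowed")
        self.keywords = keywords

        # Trie construction: state 0 is the root.
        children: list[dict[str, int]] = [{}]
        out: list[list[tuple[int, int]]] = [[]]  # state -> [(kw_id, kw_len)]
        for kw_id, kw in enumerate(keywords):
            s = 0
            for ch in kw:
                nxt = children[s].get(ch)
                if nxt is None:
                    nxt = len(children)
                    children[s][ch] = nxt
                    children.append({})
                    out.append([])
                s = nxt
            out[s].append((kw_id, len(kw)))

        # BFS failure links, folded directly into a dense goto function:
        # delta[s][ch] follows the failure chain at build time, so the scan
        # loop never does.  Characters absent from delta[s] fall back to the
        # root (correct because the root's own transitions are in delta[0]).
        fail = [0] * len(children)
        delta: list[dict[str, int]] = [dict(children[0])]
        delta.extend({} for _ in range(len(children) - 1))
        queue: deque[int] = deque(children[0].values())
        while queue:
            s = queue.popleft()
            f = fail[s]
            out[s].extend(out[f])
            merged = dict(delta[f])
            for ch, t in children[s].items():
                fail[t] = delta[f].get(ch, 0)
                merged[ch] = t
                queue.append(t)
            delta[s] = merged
        self._delta = delta
        self._out = out

    def finditer(self, target: str) -> Iterator[tuple[int, int]]:
        """Yield ``(keyword_index, start)`` for every occurrence in *target*.

        Occurrences are emitted in order of their end position.
        """
        delta = self._delta
        out = self._out
        s = 0
        for i, ch in enumerate(target):
            s = delta[s].get(ch, 0)
            if out[s]:
                for kw_id, kw_len in out[s]:
                    yield kw_id, i - kw_len + 1

    def findall(self, target: str) -> list[tuple[int, int]]:
        """Like :meth:`finditer` but materialized."""
        return list(self.finditer(target))

    def __len__(self) -> int:
        return len(self.keywords)
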