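"""Minimal bracketed constituency trees.

Parses Penn-Treebank-style s-expressions such as
``(S (NP (PRP We)) (VP (VBD studied) (NP (CD 29) (NNS patients))))``.
Only what the subject–predicate extractor needs: labels, children, leaves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Union

__all__ = ["Tree", "parse_tree", "TreeParseError"]


class TreeParseError(ValueError):
    pass


@dataclass(frozen=True)
class Tree:
    label: str
    children: tuple[Union["Tree", str], ...]

    @property
    def is_preterminal(self) -> bool:
        return len(self.children) == 1 and isinstance(self.children[0], str)

    def leaves(self) -> list[tuple[str, str]]:
        """(surface, POS) pairs in left-to-right order."""
        out: list[tuple[str, str]] = []
        if self.is_preterminal:
            out.append((self.children[0], self.label))
            return out
        for child in self.children:
            if isinstance(child, Tree):
                out.extend(child.leaves())
        return out

    def subtrees(self) -> Iterator["Tree"]:
        """Pre-order traversal including self."""
        yield self
        for child in self.children:
            if isinstance(child, Tree):
                yield from child.subtrees()

    def __str__(self) -> str:
        if self.is_preterminal:
            return f"({self.label} {self.children[0]})"
        inner = " ".join(str(c) for c in self.children)
        return f"({self.label} {inner})"


def parse_tree(text: str) -> Tree:
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise TreeParseError("empty tree string")
    pos = 0

    def parse_node() -> Tree:
        nonlocal pos
        if tokens[pos] != "(":
            raise TreeParseError(f"expected '(' at token {pos}: {tokens[pos]!r}")
        pos += 1
        if pos >= len(tokens) or tokens[pos] in "()":
            raise TreeParseError("node without label")
        label = tokens[pos]
        pos += 1
        children: list[Union[Tree, str]] = []
        while pos < len(tokens) and tokens[pos] != ")":
            if tokens[pos] == "(":
                children.append(parse_node())
            else:
                children.append(tokens[pos])
                pos += 1
        if pos >= len(tokens):
            raise TreeParseError("unbalanced parentheses")
        pos += 1  # consume ')'
        if not children:
            raise TreeParseError(f"empty node {label!r}")
        return Tree(label, tuple(children))

    root = parse_node()
    if pos != len(tokens):
        raise TreeParseError("trailing content after tree")
    return root
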