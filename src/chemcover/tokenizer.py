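"""Lexical tokenization of SMILES strings for sequence modelling.

A SMILES string is split into atom-level tokens: two-letter organic-subset
atoms ("Cl", "Br") and full bracket expressions ("[N+]", "[O-]") are single
tokens, every other character is its own token.  Sequences are framed by the
begin marker ``^`` and end marker ``$``, and mapped to integer ids under a
:class:`Vocabulary`.  Tokenization is purely lexical — chemical validity is
not required and not checked.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BEGIN",
    "END",
    "Vocabulary",
    "TokenizedSmiles",
    "tokenize",
    "build_vocabulary",
    "encode",
    "decode",
]

BEGIN = "^"
END = "$"

# bracket atoms, two-letter halogens, %nn ring closures, then any single char
_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Br|Cl|%\d{2}|.)")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; ``''.join(result) == smiles``."""
    if smiles.count("[") != smiles.count("]"):
        raise ValueError(f"unmatched bracket in {smiles!r}")
    tokens = _TOKEN_RE.findall(smiles)
    for t in tokens:
        if t == "[" or t == "]":
            raise ValueError(f"unmatched bracket in {smiles!r}")
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory with ``^``/``$`` fixed at indices 0 and 1."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens.count(BEGIN) != 1 or self.tokens.count(END) != 1:
            raise ValueError("vocabulary must contain '^' and '$' exactly once")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    @property
    def begin_id(self) -> int:
        return self.tokens.index(BEGIN)

    @property
    def end_id(self) -> int:
        return self.tokens.index(END)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"tokens": list(self.tokens)}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        data = json.loads(Path(path).read_text())
        return cls(tokens=tuple(data["tokens"]))


@dataclass(frozen=True)
class TokenizedSmiles:
    """A framed token sequence and its integer ids under a vocabulary."""

    smiles: str
    tokens: tuple[str, ...]
    ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.ids):
            raise ValueError("tokens and ids length mismatch")
        if self.tokens[0] != BEGIN or self.tokens[-1] != END:
            raise ValueError("sequence must be framed by '^' and '$'")


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Vocabulary over all tokens in ``corpus``, specials first then sorted.

    Deterministic: any ordering of the same corpus yields the same
    vocabulary, so checkpoints are reproducible.
    """
    seen: set[str] = set()
    empty = True
    for smiles in corpus:
        empty = False
        seen.update(tokenize(smiles))
    if empty:
        raise ValueError("empty corpus")
    seen.discard(BEGIN)
    seen.discard(END)
    return Vocabulary(tokens=(BEGIN, END, *sorted(seen)))


def encode(smiles: str, vocab: Vocabulary) -> TokenizedSmiles:
    """Frame and index a SMILES string; raises naming any unknown token."""
    tokens = (BEGIN, *tokenize(smiles), END)
    index = vocab.index
    ids = []
    for t in tokens:
        if t not in index:
            raise KeyError(f"token {t!r} not in vocabulary")
        ids.append(index[t])
    return TokenizedSmiles(smiles=smiles, tokens=tokens, ids=tuple(ids))


def decode(ids: Sequence[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`encode`: ids back to the SMILES string.

    Leading ``^`` and trailing ``$`` markers are stripped if present, so both
    framed and bare id sequences decode cleanly.
    """
    toks = [vocab.tokens[i] for i in ids]
    if toks and toks[0] == BEGIN:
        toks = toks[1:]
    if END in toks:
        toks = toks[: toks.index(END)]
    return "".join(toks)
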