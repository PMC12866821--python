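"""Context-free SMILES grammar, parse-tree rule sequences and one-hot arrays.

A molecule is parsed into its leftmost-derivation sequence of production
rules under a small CFG over SMILES tokens (atoms, bonds, branches, ring
closures). Replaying the sequence regenerates a SMILES string equivalent to
the input under canonicalization. The rule sequence is then one-hot encoded
as a (max_sequence_length x vocabulary_size) binary matrix, padded with a
dedicated final padding rule.

The grammar intentionally covers a practical organic subset (the built-in
synthetic fragment vocabulary is fully inside it); a character-level
tokenizer grammar is available as a fallback via :func:`character_grammar`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger

from .errors import SchemaError, SequenceLengthError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

ATOM_TOKENS = (
    "Cl", "Br", "[nH]",
    "C", "N", "O", "S", "F", "I", "P", "B",
    "c", "n", "o", "s",
)
BOND_TOKENS = ("=", "#", "-", "/", "\\")
RING_TOKENS = tuple(str(d) for d in range(1, 9))

_NONTERMINALS = ("CHAIN", "UNIT", "ATOM", "BOND", "RING", "BRANCH")


def _build_rules() -> tuple[tuple[str, tuple[str, ...]], ...]:
    rules: list[tuple[str, tuple[str, ...]]] = [
        ("CHAIN", ("UNIT", "CHAIN")),
        ("CHAIN", ("UNIT",)),
        ("UNIT", ("ATOM",)),
        ("UNIT", ("ATOM", "RING")),
        ("UNIT", ("ATOM", "RING", "RING")),
        ("UNIT", ("BOND", "ATOM")),
        ("UNIT", ("BOND", "ATOM", "RING")),
        ("UNIT", ("BRANCH",)),
        ("BRANCH", ("(", "CHAIN", ")")),
    ]
    rules += [("ATOM", (t,)) for t in ATOM_TOKENS]
    rules += [("BOND", (t,)) for t in BOND_TOKENS]
    rules += [("RING", (t,)) for t in RING_TOKENS]
    return tuple(rules)


@dataclass(frozen=True)
class SmilesGrammar:
    """Ordered production rules plus a fixed padding rule (always last)."""

    production_rules: tuple[tuple[str, tuple[str, ...]], ...] = field(
        default_factory=_build_rules
    )
    max_sequence_length: int = 277
    kind: str = "cfg"  # "cfg" | "character"

    @property
    def vocabulary_size(self) -> int:
        return len(self.production_rules) + 1  # + padding rule

    @property
    def pad_index(self) -> int:
        return len(self.production_rules)

    @property
    def hash(self) -> str:
        payload = repr((self.production_rules, self.max_sequence_length, self.kind))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_grammar(max_sequence_length: int = 277) -> SmilesGrammar:
    return SmilesGrammar(max_sequence_length=max_sequence_length)


def character_grammar(max_sequence_length: int = 277) -> SmilesGrammar:
    """Fallback: one production per token; the 'derivation' is the token list."""
    tokens = ATOM_TOKENS + BOND_TOKENS + RING_TOKENS + ("(", ")")
    rules = tuple(("TOK", (t,)) for t in tokens)
    return SmilesGrammar(
        production_rules=rules, max_sequence_length=max_sequence_length, kind="character"
    )


@dataclass
class OneHotEncoding:
    """Row-stochastic binary matrix over grammar rules, padded to full length."""

    matrix: np.ndarray
    source_smiles: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        row_sums = self.matrix.sum(axis=1)
        if not np.all(row_sums == 1):
            raise SchemaError("every one-hot row must sum to exactly 1")


def tokenize(smiles: str) -> list[tuple[str, int]]:
    """Split a SMILES string into (token, char_position) pairs."""
    tokens: list[tuple[str, int]] = []
    i = 0
    multi = ("[nH]", "Cl", "Br")
    single = set("CNOSFIPBcnos=#-/\\()") | set("12345678")
    while i < len(smiles):
        for m in multi:
            if smiles.startswith(m, i):
                tokens.append((m, i))
                i += len(m)
                break
        else:
            ch = smiles[i]
            if ch not in single:
                raise SmilesParseError(
                    f"unrecognized SMILES token {ch!r} at position {i}", position=i
                )
            tokens.append((ch, i))
            i += 1
    return tokens


class _Parser:
    """Recursive-descent parser emitting the leftmost-derivation rule indices."""

    def __init__(self, tokens: list[tuple[str, int]], grammar: SmilesGrammar):
        self.tokens = tokens
        self.pos = 0
        self.grammar = grammar
        # terminal -> rule index, per nonterminal
        self.atom_rule = {}
        self.bond_rule = {}
        self.ring_rule = {}
        for idx, (lhs, rhs) in enumerate(grammar.production_rules):
            if lhs == "ATOM":
                self.atom_rule[rhs[0]] = idx
            elif lhs == "BOND":
                self.bond_rule[rhs[0]] = idx
            elif lhs == "RING":
                self.ring_rule[rhs[0]] = idx
        self.open_rings: set[str] = set()

    def _peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _take(self) -> tuple[str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def _fail(self, message: str) -> None:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.tokens)
        raise SmilesParseError(f"{message} at position {at}", position=at)

    def _ring_digit(self) -> int:
        tok, _ = self._take()
        if tok in self.open_rings:
            self.open_rings.discard(tok)
        else:
            self.open_rings.add(tok)
        return self.ring_rule[tok]

    def parse_unit(self) -> list[int]:
        tok = self._peek()
        if tok == "(":
            self._take()
            inner = self.parse_chain()
            if self._peek() != ")":
                self._fail("expected ')'")
            self._take()
            return [7, 8] + inner
        rules: list[int] = []
        if tok in self.bond_rule:
            bond_idx = self.bond_rule[tok]
            self._take()
            atom = self._peek()
            if atom not in self.atom_rule:
                self._fail("expected atom after bond symbol")
            atom_idx = self.atom_rule[atom]
            self._take()
            if self._peek() in self.ring_rule:
                return [6, bond_idx, atom_idx, self._ring_digit()]
            return [5, bond_idx, atom_idx]
        if tok in self.atom_rule:
            atom_idx = self.atom_rule[tok]
            self._take()
            digits = []
            while self._peek() in self.ring_rule and len(digits) < 2:
                digits.append(self._ring_digit())
            unit_rule = {0: 2, 1: 3, 2: 4}[len(digits)]
            return [unit_rule, atom_idx] + digits
        self._fail(f"unexpected token {tok!r}")
        raise AssertionError  # unreachable

    def parse_chain(self) -> list[int]:
        seq: list[int] = []
        while True:
            unit = self.parse_unit()
            more = self._peek() is not None and self._peek() != ")"
            seq += ([0] if more else [1]) + unit
            if not more:
                return seq


def parse_to_rule_sequence(smiles: str, grammar: SmilesGrammar) -> list[int]:
    """Parse a valid SMILES into its leftmost-derivation rule index sequence.

    Raises :class:`SmilesParseError` (with position where known) for invalid
    input and :class:`SequenceLengthError` when the derivation exceeds
    ``grammar.max_sequence_length``.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES", position=0)
    tokens = tokenize(smiles)
    if grammar.kind == "character":
        rule_of = {rhs[0]: i for i, (_, rhs) in enumerate(grammar.production_rules)}
        seq = [rule_of[t] for t, _ in tokens]
    else:
        parser = _Parser(tokens, grammar)
        seq = parser.parse_chain()
        if parser.pos != len(tokens):
            parser._fail("trailing input")
        if parser.open_rings:
            raise SmilesParseError(
                f"unclosed ring bond(s): {sorted(parser.open_rings)}", position=None
            )
    if Chem.MolFromSmiles(smiles) is None:
        raise SmilesParseError(f"chemically invalid SMILES {smiles!r}", position=None)
    if len(seq) > grammar.max_sequence_length:
        raise SequenceLengthError(
            f"derivation length {len(seq)} exceeds max_sequence_length "
            f"{grammar.max_sequence_length}"
        )
    return seq


def replay_rules(sequence: list[int], grammar: SmilesGrammar) -> str:
    """Expand a leftmost-derivation rule sequence back into a SMILES string."""
    if grammar.kind == "character":
        return "".join(grammar.production_rules[i][1][0] for i in sequence)
    nonterminals = set(_NONTERMINALS)
    stack = ["CHAIN"]
    out: list[str] = []
    for idx in sequence:
        if idx == grammar.pad_index:
            break
        lhs, rhs = grammar.production_rules[idx]
        while stack and stack[-1] not in nonterminals:
            out.append(stack.pop())
        if not stack or stack[-1] != lhs:
            raise SchemaError(
                f"rule {idx} ({lhs}) does not match leftmost nonterminal "
                f"{stack[-1] if stack else 'EOF'!r}"
            )
        stack.pop()
        stack.extend(reversed(rhs))
    while stack and stack[-1] not in nonterminals:
        out.append(stack.pop())
    if stack:
        raise SchemaError(f"incomplete derivation; unexpanded symbols {stack!r}")
    return "".join(out)


def one_hot(sequence: list[int], grammar: SmilesGrammar, source_smiles: str = "") -> OneHotEncoding:
    """Rule sequence -> (max_sequence_length x vocabulary_size) one-hot matrix."""
    L, V = grammar.max_sequence_length, grammar.vocabulary_size
    if len(sequence) > L:
        raise SequenceLengthError(f"sequence length {len(sequence)} exceeds {L}")
    matrix = np.zeros((L, V), dtype=np.int8)
    for r, idx in enumerate(sequence):
        if not 0 <= idx < V:
            raise SchemaError(f"rule index {idx} out of range (vocabulary {V})")
        matrix[r, idx] = 1
    matrix[len(sequence):, grammar.pad_index] = 1
    return OneHotEncoding(matrix=matrix, source_smiles=source_smiles)


def decode_one_hot(encoding: OneHotEncoding, grammar: SmilesGrammar) -> list[int]:
    """Invert :func:`one_hot`, stripping trailing padding rows."""
    indices = np.argmax(encoding.matrix, axis=1).tolist()
    while indices and indices[-1] == grammar.pad_index:
        indices.pop()
    return indices


def encode_smiles(smiles: str, grammar: SmilesGrammar) -> OneHotEncoding:
    """Convenience: parse + one-hot in one call."""
    return one_hot(parse_to_rule_sequence(smiles, grammar), grammar, source_smiles=smiles)
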