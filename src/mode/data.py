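"""Corpus records, vocabulary, tokenized-sequence I/O and batch collation.

A corpus is a JSON-Lines file, one report per line, with four fields:
``finding``, ``impression``, ``treatment`` (token id arrays) and
``severity`` (an integer in 0..5).  The vocabulary is a plain
token-per-line sidecar file with the four reserved tokens first:
``<pad>``, ``<unk>``, ``<start>``, ``<end>``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

PAD, UNK, START, END = "<pad>", "<unk>", "<start>", "<end>"
RESERVED = (PAD, UNK, START, END)
PAD_ID, UNK_ID, START_ID, END_ID = 0, 1, 2, 3


@dataclass
class ReportRecord:
    """One report: three token-id sequences plus the ordinal severity label."""

    finding: List[int]
    impression: List[int]
    treatment: List[int]
    severity: int

    def validate(self) -> None:
        for name in ("finding", "impression", "treatment"):
            seq = getattr(self, name)
            if len(seq) == 0:
                raise ValueError(f"{name} sequence is empty")
        if not isinstance(self.severity, (int, np.integer)) or \
                isinstance(self.severity, bool):
            raise ValueError(f"severity must be an integer, got {self.severity!r}")
        if not 0 <= self.severity <= 5:
            raise ValueError(f"severity {self.severity} outside 0..5")


class Vocabulary:
    """Bijective token <-> id map with fixed reserved ids."""

    def __init__(self, tokens: Sequence[str]):
        if list(tokens[:4]) != list(RESERVED):
            tokens = list(RESERVED) + [t for t in tokens if t not in RESERVED]
        self.tokens: List[str] = list(tokens)
        self.token_to_id: Dict[str, int] = {t: i for i, t in enumerate(self.tokens)}
        if len(self.token_to_id) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "Vocabulary":
        seen: List[str] = []
        got = set(RESERVED)
        for t in tokens:
            if t not in got:
                got.add(t)
                seen.append(t)
        return cls(list(RESERVED) + seen)

    def encode(self, tokens: Sequence[str], flags: bool = False) -> List[int]:
        ids = [self.token_to_id.get(t, UNK_ID) for t in tokens]
        if flags:
            ids = [START_ID] + ids + [END_ID]
        return ids

    def decode(self, ids: Sequence[int]) -> List[str]:
        return [self.tokens[i] for i in ids
                if 0 <= i < len(self.tokens) and i not in (PAD_ID, START_ID, END_ID)]

    def save(self, path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        tokens = Path(path).read_text().splitlines()
        return cls(tokens)


class CorpusFormatError(ValueError):
    pass


_FIELDS = ("finding", "impression", "treatment", "severity")


def read_corpus(path) -> List[ReportRecord]:
    """Read a JSON-Lines corpus; malformed lines are reported by number."""
    records: List[ReportRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            for field in _FIELDS:
                if field not in obj:
                    raise CorpusFormatError(f"line {lineno}: missing field {field!r}")
            rec = ReportRecord(finding=list(map(int, obj["finding"])),
                               impression=list(map(int, obj["impression"])),
                               treatment=list(map(int, obj["treatment"])),
                               severity=obj["severity"])
            try:
                if not isinstance(obj["severity"], int) or isinstance(obj["severity"], bool):
                    raise ValueError("severity must be an integer")
                rec.validate()
            except ValueError as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_corpus(records: Sequence[ReportRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps({"finding": rec.finding,
                                 "impression": rec.impression,
                                 "treatment": rec.treatment,
                                 "severity": int(rec.severity)}) + "\n")


def pad_batch(seqs: Sequence[Sequence[int]]) -> Tuple[np.ndarray, np.ndarray]:
    """Right-pad with <pad>; return (ids (B,T), mask (B,T))."""
    T = max(len(s) for s in seqs)
    ids = np.full((len(seqs), T), PAD_ID, dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s
        mask[i, :len(s)] = True
    return ids, mask


def build_teacher(targets: Sequence[Sequence[int]], flags: bool
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shifted decoder inputs and gold outputs for teacher forcing.

    With flags: input = <start> + y, output = y + <end>.  Without flags the
    input is y shifted right behind a pad placeholder and the output is y.
    Returns (teacher_in, teacher_out, loss_mask).
    """
    ins, outs = [], []
    for y in targets:
        y = list(y)
        if flags:
            ins.append([START_ID] + y)
            outs.append(y + [END_ID])
        else:
            ins.append([PAD_ID] + y[:-1])
            outs.append(y)
    t_in, _ = pad_batch(ins)
    t_out, mask = pad_batch(outs)
    return t_in, t_out, mask
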