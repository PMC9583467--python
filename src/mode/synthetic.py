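"""Synthetic ultrasound-report corpus with learnable cross-field structure.

The real corpus this emulates is a set of 513 character-tokenized thyroid
ultrasound reports, each carrying a Finding, an Impression, a Treatment
recommendation and a 6-level severity label, with mean field lengths of
about 60 / 31 / 53 tokens and per-field vocabularies of roughly 353 / 263 /
277 distinct tokens.  The generator reproduces that schema and scale from a
latent clinical attribute vector per report (nodule size class, margin
regularity, calcification, echogenicity, vascularity, nodule count):

* the Finding renders every attribute as a fixed phrase, interleaved with
  Poisson-jittered filler and light token-substitution noise;
* the Impression is a noise-free deterministic summary of the attributes;
* the severity label is a deterministic score of the attributes;
* the Treatment is a noise-free function of the severity band and the
  attributes.

Because Impression, severity and Treatment are all functions of attributes
that are observable in the Finding, the auxiliary tasks and the main task
genuinely share structure — the precondition for parameter-sharing
transfer to be measurable.  The whole corpus is a pure function of the
generator configuration (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .data import ReportRecord, Vocabulary

ATTR_CARDINALITIES = {"size_class": 3, "margin": 2, "calcification": 2,
                      "hypoechoic": 2, "vascular": 2, "nodule_count": 3}


@dataclass(frozen=True)
class AttributeVector:
    """Latent clinical attributes of one synthetic report."""

    size_class: int      # 0 small, 1 medium, 2 large
    margin: int          # 0 regular, 1 irregular
    calcification: int   # 0 absent, 1 present
    hypoechoic: int      # 0 no, 1 yes
    vascular: int        # 0 no, 1 yes
    nodule_count: int    # 1..3

    def as_tuple(self) -> Tuple[int, ...]:
        return (self.size_class, self.margin, self.calcification,
                self.hypoechoic, self.vascular, self.nodule_count)

    def validate(self) -> None:
        if not 0 <= self.size_class <= 2:
            raise ValueError("size_class outside 0..2")
        for name in ("margin", "calcification", "hypoechoic", "vascular"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if not 1 <= self.nodule_count <= 3:
            raise ValueError("nodule_count outside 1..3")


@dataclass
class GeneratorConfig:
    """Scale and noise knobs of the synthetic corpus."""

    n_records: int = 513
    mean_finding_len: int = 60
    mean_impression_len: int = 31
    mean_treatment_len: int = 53
    finding_pool: int = 353
    impression_pool: int = 263
    treatment_pool: int = 277
    noise_rate: float = 0.02
    split_fractions: Tuple[float, float, float] = (0.70, 0.10, 0.20)
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 10:
            raise ValueError("n_records must be >= 10")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")


def sample_attributes(rng: np.random.Generator) -> AttributeVector:
    """Independent categorical draws; every severity label has mass >= 0.02."""
    return AttributeVector(size_class=int(rng.integers(0, 3)),
                           margin=int(rng.integers(0, 2)),
                           calcification=int(rng.integers(0, 2)),
                           hypoechoic=int(rng.integers(0, 2)),
                           vascular=int(rng.integers(0, 2)),
                           nodule_count=int(rng.integers(1, 4)))


def compute_severity(a: AttributeVector) -> int:
    """Deterministic 6-level severity score of the attributes."""
    a.validate()
    raw = a.size_class + 2 * a.margin + a.calcification + a.hypoechoic + a.vascular
    return min(5, raw)


def severity_band(severity: int) -> int:
    """Treatment bands: 0 for severity 0-1, 1 for 2-3, 2 for 4-5."""
    return min(severity // 2, 2)


# ---------------------------------------------------------------------------
# phrase banks and rendering


def _field_tokens(prefix: str, pool: int) -> List[str]:
    return [f"{prefix}{i:03d}" for i in range(pool)]


class _PhraseBanks:
    """Fixed per-corpus phrase banks, a pure function of the config seed."""

    FINDING_PHRASE_LEN = 3
    NODULE_PHRASE_LEN = 2
    IMPR_HEADER_LEN = 2
    IMPR_BAND_LEN = 3
    IMPR_ATTR_LEN = 4
    TREAT_BAND_LEN = 6
    TREAT_ATTR_LEN = 4

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        rng = np.random.default_rng([cfg.seed, 0xBA])
        self.find_tokens = _field_tokens("f", cfg.finding_pool)
        self.impr_tokens = _field_tokens("i", cfg.impression_pool)
        self.treat_tokens = _field_tokens("t", cfg.treatment_pool)
        draw = lambda pool, k: [pool[j] for j in rng.integers(0, len(pool), k)]
        self.finding_attr: Dict[Tuple[str, int], List[str]] = {}
        for name, card in ATTR_CARDINALITIES.items():
            for v in range(card):
                L = (self.NODULE_PHRASE_LEN if name == "nodule_count"
                     else self.FINDING_PHRASE_LEN)
                self.finding_attr[(name, v)] = draw(self.find_tokens, L)
        self.impr_header = draw(self.impr_tokens, self.IMPR_HEADER_LEN)
        self.impr_band = {b: draw(self.impr_tokens, self.IMPR_BAND_LEN)
                          for b in range(3)}
        self.impr_attr = {k: draw(self.impr_tokens, self.IMPR_ATTR_LEN)
                          for k in self.finding_attr if k[0] != "nodule_count"}
        self.treat_band = {b: draw(self.treat_tokens, self.TREAT_BAND_LEN)
                           for b in range(3)}
        self.treat_attr = {k: draw(self.treat_tokens, self.TREAT_ATTR_LEN)
                           for k in self.finding_attr if k[0] != "nodule_count"}


def _attr_rng(cfg: GeneratorConfig, field_id: int, a: AttributeVector
              ) -> np.random.Generator:
    """Deterministic stream keyed by (config seed, field, attribute combo)."""
    return np.random.default_rng([cfg.seed, field_id, *a.as_tuple()])


def render_finding(a: AttributeVector, cfg: GeneratorConfig,
                   rng: np.random.Generator,
                   banks: "_PhraseBanks" = None) -> List[str]:
    """Attribute phrases + Poisson filler + substitution noise."""
    a.validate()
    banks = banks or _PhraseBanks(cfg)
    phrases = []
    for name in ("size_class", "margin", "calcification", "hypoechoic",
                 "vascular"):
        phrases.append(banks.finding_attr[(name, getattr(a, name))])
    phrases.append(banks.finding_attr[("nodule_count", a.nodule_count - 1)])
    core = [tok for ph in phrases for tok in ph]
    lam = max(1, cfg.mean_finding_len - len(core))
    n_fill = int(rng.poisson(lam))
    filler = [banks.find_tokens[j]
              for j in rng.integers(0, len(banks.find_tokens), n_fill)]
    # attribute phrases stay contiguous; filler lands at random positions
    tokens = core.copy()
    for tok in filler:
        pos = int(rng.integers(0, len(tokens) + 1))
        tokens.insert(pos, tok)
    noise = rng.random(len(tokens)) < cfg.noise_rate
    for idx in np.flatnonzero(noise):
        tokens[idx] = banks.find_tokens[int(rng.integers(0, len(banks.find_tokens)))]
    return tokens


def derive_impression(a: AttributeVector, cfg: GeneratorConfig,
                      banks: "_PhraseBanks" = None) -> List[str]:
    """Noise-free attribute summary; length 29 + nodule_count (mean 31)."""
    a.validate()
    banks = banks or _PhraseBanks(cfg)
    sev = compute_severity(a)
    band = severity_band(sev)
    tokens = list(banks.impr_header) + list(banks.impr_band[band])
    for name in ("size_class", "margin", "calcification", "hypoechoic",
                 "vascular"):
        tokens += banks.impr_attr[(name, getattr(a, name))]
    # deterministic per-combo style tokens fill to the target length
    style_rng = _attr_rng(cfg, 1, a)
    target = cfg.mean_impression_len - 2 + a.nodule_count
    n_fill = max(0, target - len(tokens))
    tokens += [banks.impr_tokens[j]
               for j in style_rng.integers(0, len(banks.impr_tokens), n_fill)]
    return tokens


def derive_treatment(a: AttributeVector, severity: int, cfg: GeneratorConfig,
                     banks: "_PhraseBanks" = None) -> List[str]:
    """Noise-free phrase bank keyed by severity band plus qualifiers."""
    a.validate()
    banks = banks or _PhraseBanks(cfg)
    band = severity_band(severity)
    tokens = list(banks.treat_band[band])
    for name in ("size_class", "margin", "calcification", "hypoechoic",
                 "vascular"):
        tokens += banks.treat_attr[(name, getattr(a, name))]
    style_rng = _attr_rng(cfg, 2, a)
    target = cfg.mean_treatment_len - 1 + a.size_class
    n_fill = max(0, target - len(tokens))
    tokens += [banks.treat_tokens[j]
               for j in style_rng.integers(0, len(banks.treat_tokens), n_fill)]
    return tokens


def build_vocabulary(cfg: GeneratorConfig) -> Vocabulary:
    """The full token inventory is known from the config alone."""
    return Vocabulary.from_tokens(_field_tokens("f", cfg.finding_pool)
                                  + _field_tokens("i", cfg.impression_pool)
                                  + _field_tokens("t", cfg.treatment_pool))


def generate_corpus(cfg: GeneratorConfig) -> List[ReportRecord]:
    """Exactly ``cfg.n_records`` schema-complete records, seed-deterministic."""
    cfg.validate()
    banks = _PhraseBanks(cfg)
    vocab = build_vocabulary(cfg)
    rng = np.random.default_rng([cfg.seed, 0xC0])
    records: List[ReportRecord] = []
    for _ in range(cfg.n_records):
        a = sample_attributes(rng)
        sev = compute_severity(a)
        rec = ReportRecord(
            finding=vocab.encode(render_finding(a, cfg, rng, banks)),
            impression=vocab.encode(derive_impression(a, cfg, banks)),
            treatment=vocab.encode(derive_treatment(a, sev, cfg, banks)),
            severity=sev)
        rec.validate()
        records.append(rec)
    return records


def split_corpus(records: Sequence[ReportRecord], cfg: GeneratorConfig
                 ) -> Tuple[List[ReportRecord], List[ReportRecord], List[ReportRecord]]:
    """Seeded shuffle into train / dev / test (70 / 10 / 20 by default)."""
    n = len(records)
    n_dev = round(cfg.split_fractions[1] * n)
    n_test = round(cfg.split_fractions[2] * n)
    if n - n_dev - n_test <= 0 or n_dev < 1 or n_test < 1:
        raise ValueError(f"corpus of {n} records too small for the split")
    order = np.random.default_rng([cfg.seed, 0x5F]).permutation(n)
    shuffled = [records[i] for i in order]
    dev = shuffled[:n_dev]
    test = shuffled[n_dev:n_dev + n_test]
    train = shuffled[n_dev + n_test:]
    return train, dev, test
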