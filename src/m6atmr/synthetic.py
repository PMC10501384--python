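"""Synthetic benchmark datasets with a planted m6A-like motif.

Each dataset is a balanced set of fixed-length RNA windows with a central
adenosine (the candidate site).  Positives carry a consensus motif context
planted symmetrically around the center, with each non-central motif
position substituted at rate ``eps`` (a uniformly chosen different base);
negatives are pure background with the central A but no planted motif.  The
default motif is a 21-nt GGACU-centered consensus context, long enough that
the clean (eps = 0) datasets remain strongly separable after the pipeline's
convex feature fusion, which is the regime the recovery checks assume;
raising eps toward 0.5 erases the signal continuously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmer import BASES
from .sequences import RnaSequence

__all__ = ["SynthConfig", "generate", "difficulty_sweep", "DEFAULT_MOTIF"]

# GGACU consensus embedded in a 21-nt context, central A at the window center
DEFAULT_MOTIF = "GCAGUCUGGGACUGGAUCGUA"


@dataclass
class SynthConfig:
    m: int = 2100
    n: int = 101
    motif: str = DEFAULT_MOTIF
    eps: float = 0.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n % 2 == 0:
            raise ValueError("n must be odd so the central site is defined")
        if len(self.motif) > self.n:
            raise ValueError("motif longer than the sequence window")
        if len(self.motif) % 2 == 0 or self.motif[len(self.motif) // 2] != "A":
            raise ValueError("motif must have odd length with a central A")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must lie in [0, 0.5)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be a probability vector over ACGU")


def generate(cfg: SynthConfig) -> tuple[list[RnaSequence], pd.DataFrame]:
    """Draw one dataset; returns (records, truth table).

    The truth table records id, label and the planted motif's start offset
    (-1 for negatives) so feature-attribution checks are possible.
    """
    rng = np.random.default_rng(cfg.seed)
    center = cfg.n // 2
    half = len(cfg.motif) // 2
    start = center - half
    n_pos = round(cfg.m * cfg.class_balance)
    labels = np.array([1] * n_pos + [0] * (cfg.m - n_pos))
    rng.shuffle(labels)

    base_arr = np.array(list(BASES))
    motif_idx = np.array([BASES.index(b) for b in cfg.motif])
    records: list[RnaSequence] = []
    truth_rows = []
    for i, label in enumerate(labels):
        seq = rng.choice(4, size=cfg.n, p=cfg.background)
        if label == 1:
            planted = motif_idx.copy()
            for j in range(len(planted)):
                if j == half:
                    continue  # the central A is never substituted
                if rng.random() < cfg.eps:
                    planted[j] = rng.choice([b for b in range(4) if b != motif_idx[j]])
            seq[start:start + len(planted)] = planted
        seq[center] = 0  # central A in both classes
        residues = "".join(base_arr[seq])
        rec = RnaSequence(id=f"seq{i:05d}", residues=residues, label=int(label))
        records.append(rec)
        truth_rows.append({"id": rec.id, "label": int(label),
                           "motif_start": start if label == 1 else -1})
    return records, pd.DataFrame(truth_rows)


def difficulty_sweep(cfg: SynthConfig, eps_grid=(0.0, 0.1, 0.2, 0.3, 0.4)
                     ) -> dict[float, tuple[list[RnaSequence], pd.DataFrame]]:
    """One dataset per substitution rate, with derived per-dataset seeds."""
    out = {}
    for k, eps in enumerate(eps_grid):
        if not 0.0 <= eps < 0.5:
            raise ValueError("eps grid must lie in [0, 0.5)")
        sub = SynthConfig(m=cfg.m, n=cfg.n, motif=cfg.motif, eps=eps,
                          background=cfg.background,
                          class_balance=cfg.class_balance,
                          seed=(cfg.seed + 7919 * k) % (2 ** 31))
        out[eps] = generate(sub)
    return out
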