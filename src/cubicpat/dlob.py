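"""Directed Lobish (DLob): symbolic, lobe-level readout of selected features.

Every channel of a montage is assigned a cortical-lobe symbol through a
lookup table (frontal/temporal/parietal/occipital/central, left/right/
midline: FL, FR, Fz, TL, TR, PL, PR, Pz, OL, OR, Oz, CL, CR, Cz).  A
selected feature index is a base-n code of a channel triplet, so digit
separation

    ch_j = floor((value - 1) / n**(j-1)) mod n + 1,   j = 1, 2, 3

recovers the three channels, and the LUT turns each selected feature into
three lobe symbols.  The concatenated symbol string is summarized by a
symbol histogram, an adjacent-pair transition table (the cortical
connectome), its Shannon entropy in bits, and the complexity ratio
entropy / log2(alphabet size).

Note the digit formula yields the triplet in *reverse* encoding order;
by default the digits are re-reversed so symbols appear in the order the
channels were ranked.  Histogram and entropy are order-independent, the
transition table is not, so the order is configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DLOB_SYMBOLS",
    "LUT32",
    "LUT14",
    "DLobSequence",
    "TransitionTable",
    "decode_feature_index",
    "build_sequence",
    "transition_table",
    "sequence_entropy",
    "complexity_ratio",
    "to_graph",
    "export_connectome",
    "load_lut",
]

#: canonical symbol order (fixes histogram / transition-table axes)
DLOB_SYMBOLS = ("FL", "FR", "Fz", "TL", "TR", "PL", "PR", "Pz",
                "OL", "OR", "Oz", "CL", "CR", "Cz")

#: lobe symbol per channel of the 32-channel montage
#: (Cz, Fz, Fp1, F7, F3, FC1, C3, FC5, FT9, T7, CP5, CP1, P3, P7, PO9, O1,
#:  Pz, Oz, O2, PO10, P8, P4, CP2, CP6, T8, FT10, FC6, C4, FC2, F4, F8, Fp2)
LUT32 = ("Cz", "Fz", "FL", "FL", "FL", "FL", "CL", "FL", "FL", "TL", "CL",
         "CL", "PL", "PL", "PL", "OL", "Pz", "Oz", "OR", "PR", "PR", "PR",
         "CR", "CR", "TR", "FR", "FR", "CR", "FR", "FR", "FR", "FR")

#: lobe symbol per channel of the 14-channel montage
#: (AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4)
LUT14 = ("FL", "FL", "FL", "FL", "TL", "PL", "OL", "OR", "PR", "TR",
         "FR", "FR", "FR", "FR")


def _validate_lut(lut) -> tuple[str, ...]:
    lut = tuple(lut)
    bad = [s for s in lut if s not in DLOB_SYMBOLS]
    if bad:
        raise ValueError(f"unknown lobe symbols in LUT: {bad}")
    return lut


def load_lut(source: str | Path) -> tuple[str, ...]:
    """Resolve a LUT choice: 'lut14', 'lut32', or a one-column CSV of symbols."""
    if str(source).lower() == "lut14":
        return LUT14
    if str(source).lower() == "lut32":
        return LUT32
    path = Path(source)
    if not path.exists():
        raise ValueError(f"unknown LUT {source!r}: not 'lut14'/'lut32' and no such file")
    symbols = [s.strip() for s in path.read_text().split() if s.strip()]
    return _validate_lut(symbols)


@dataclass
class DLobSequence:
    """Lobe-symbol string decoded from selected feature indices."""

    symbols: list[str]
    source_indices: np.ndarray
    n_channels: int
    alphabet: tuple[str, ...]  # distinct LUT symbols in canonical order

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "".join(self.symbols)


@dataclass
class TransitionTable:
    """Symbol histogram, adjacent-pair transition counts and entropy."""

    counts: pd.DataFrame      # square, alphabet x alphabet
    histogram: pd.Series      # per-symbol counts over the alphabet
    entropy_bits: float
    alphabet: tuple[str, ...]


def decode_feature_index(value: int, n: int) -> tuple[int, int, int]:
    """Digit-separate a 1-based feature identity into its three channel indices.

    The returned triplet is in digit order (least-significant first), which
    is the reverse of the order in which the channels were encoded.
    """
    value = int(value)
    if not 1 <= value <= n**3:
        raise IndexError(f"feature identity {value} out of range 1..{n**3}")
    v = value - 1
    return tuple(int((v // n**j) % n) + 1 for j in range(3))


def build_sequence(
    selected_indices,
    lut,
    *,
    zero_based: bool = True,
    order: str = "encoding",
) -> DLobSequence:
    """Decode selected feature indices into a lobe-symbol sequence (3 per feature).

    Parameters
    ----------
    selected_indices
        Feature bin indices; 0-based by default (set ``zero_based=False``
        for 1-based identities).
    order
        ``"encoding"`` (default) emits symbols in the order the channels
        were ranked at encoding time; ``"digit"`` keeps raw digit order
        (the reverse).
    """
    lut = _validate_lut(lut)
    n = len(lut)
    if order not in ("encoding", "digit"):
        raise ValueError("order must be 'encoding' or 'digit'")
    idx = np.asarray(list(selected_indices), dtype=np.int64)
    symbols: list[str] = []
    for raw in idx:
        value = int(raw) + 1 if zero_based else int(raw)
        channels = decode_feature_index(value, n)
        if order == "encoding":
            channels = channels[::-1]
        symbols.extend(lut[c - 1] for c in channels)
    alphabet = tuple(s for s in DLOB_SYMBOLS if s in set(lut))
    return DLobSequence(symbols=symbols, source_indices=idx, n_channels=n,
                        alphabet=alphabet)


def transition_table(seq: DLobSequence) -> TransitionTable:
    """Histogram, adjacent-pair transition counts and entropy of a symbol sequence."""
    alphabet = seq.alphabet
    pos = {s: i for i, s in enumerate(alphabet)}
    hist = np.zeros(len(alphabet), dtype=int)
    counts = np.zeros((len(alphabet), len(alphabet)), dtype=int)
    for s in seq.symbols:
        hist[pos[s]] += 1
    for a, b in zip(seq.symbols[:-1], seq.symbols[1:]):
        counts[pos[a], pos[b]] += 1
    entropy = sequence_entropy(hist) if hist.sum() > 0 else 0.0
    return TransitionTable(
        counts=pd.DataFrame(counts, index=list(alphabet), columns=list(alphabet)),
        histogram=pd.Series(hist, index=list(alphabet)),
        entropy_bits=entropy,
        alphabet=alphabet,
    )


def sequence_entropy(histogram) -> float:
    """Shannon entropy (bits) of a symbol histogram: -sum p*log2(p) over nonzero bins."""
    h = np.asarray(histogram, dtype=float)
    if (h < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram is empty; entropy undefined")
    p = h[h > 0] / total
    return float(-(p * np.log2(p)).sum())


def complexity_ratio(entropy_bits: float, alphabet_size: int) -> float:
    """Entropy as a percentage of the alphabet's maximum entropy log2(size)."""
    if alphabet_size < 2:
        raise ValueError("alphabet size must be >= 2")
    max_entropy = float(np.log2(alphabet_size))
    if entropy_bits < 0 or entropy_bits > max_entropy + 1e-9:
        raise ValueError(
            f"entropy {entropy_bits} outside [0, log2({alphabet_size}) = {max_entropy:.4f}]"
        )
    return 100.0 * entropy_bits / max_entropy


def to_graph(table: TransitionTable) -> nx.DiGraph:
    """Directed weighted connectome: used symbols as nodes, transition counts as edges."""
    g = nx.DiGraph()
    for s in table.alphabet:
        if table.histogram[s] > 0:
            g.add_node(s, count=int(table.histogram[s]))
    for a in table.alphabet:
        for b in table.alphabet:
            w = int(table.counts.at[a, b])
            if w > 0:
                g.add_edge(a, b, weight=w)
    return g


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    lines = ["digraph connectome {"]
    for node, data in g.nodes(data=True):
        lines.append(f'  "{node}" [count={data.get("count", 0)}];')
    for a, b, data in g.edges(data=True):
        w = data.get("weight", 1)
        lines.append(f'  "{a}" -> "{b}" [weight={w}, label="{w}"];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def export_connectome(table: TransitionTable, path: str | Path, fmt: str = "graphml"):
    """Write the connectome graph as GraphML or DOT; returns the graph."""
    g = to_graph(table)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(g, path)
    else:
        raise ValueError(f"unknown connectome format {fmt!r}; supported: graphml, dot")
    return g


def summary_dict(table: TransitionTable) -> dict:
    """JSON-ready summary: entropy, alphabet size and complexity percentage."""
    return {
        "entropy_bits": float(table.entropy_bits),
        "alphabet_size": len(table.alphabet),
        "complexity_percent": complexity_ratio(table.entropy_bits, len(table.alphabet))
        if len(table.alphabet) >= 2
        else float("nan"),
    }


def save_summary(table: TransitionTable, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary_dict(table), indent=1))
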