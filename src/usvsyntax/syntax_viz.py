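"""Syntax diagrams as Graphviz DOT text.

Nodes are the syllable categories plus silence; each directed edge is a
transition whose group-mean conditional probability strictly exceeds the
cutoff (default 0.05, so rare transitions are hidden), with pen width
proportional to the probability and the value printed to two decimals.
"""

from __future__ import annotations

import numpy as np

from usvsyntax.syntax_stats import SILENCE, STATES

__all__ = ["to_dot"]

_NODE_NAMES = {s: s for s in STATES}
_NODE_NAMES[SILENCE] = "silence"


def to_dot(
    prob_matrix: np.ndarray,
    cutoff: float = 0.05,
    thickness_scale: float = 10.0,
    split_silence: bool = False,
    name: str = "syntax",
) -> str:
    """Render a conditional-probability matrix as DOT text.

    Only transitions with probability strictly above ``cutoff`` are drawn.
    With ``split_silence`` the silence state is drawn as separate start
    (out-edges) and end (in-edges) nodes.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    if thickness_scale <= 0:
        raise ValueError("thickness_scale must be positive")
    p = np.asarray(prob_matrix, dtype=float)
    if p.shape != (5, 5):
        raise ValueError("expected a 5x5 probability matrix over (s, d, u, m, X)")

    def node(state: str, role: str) -> str:
        if state != SILENCE or not split_silence:
            return _NODE_NAMES[state]
        return "silence_start" if role == "start" else "silence_end"

    lines = [f"digraph {name} {{", "  rankdir=LR;"]
    nodes: list[str] = []
    for s in STATES:
        if s == SILENCE and split_silence:
            nodes.extend(["silence_start", "silence_end"])
        else:
            nodes.append(_NODE_NAMES[s])
    for n in nodes:
        lines.append(f'  {n} [shape=circle, label="{n}"];')
    for i, a in enumerate(STATES):
        for j, b in enumerate(STATES):
            v = p[i, j]
            if np.isnan(v) or v <= cutoff:
                continue
            width = v * thickness_scale
            lines.append(
                f'  {node(a, "start")} -> {node(b, "end")} '
                f'[penwidth={width:.3f}, label="{v:.2f}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
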