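"""Serialising hybridization networks: extended Newick and flat TSV."""

from __future__ import annotations

from .hybrid_detection import HybridizationNetwork
from .nj_engine import TreeNode, _fmt_len

__all__ = ["to_enewick", "reticulations_frame", "write_reticulations_tsv"]

_TSV_COLUMNS = [
    "recipient",
    "donor1",
    "donor1_members",
    "degree1",
    "donor2",
    "donor2_members",
    "degree2",
    "score",
    "step",
    "round",
]


def to_enewick(net: HybridizationNetwork) -> str:
    """Extended-Newick string with #H reticulation nodes.

    Each reticulation r gets a hybrid node ``#Hr``; its first occurrence
    (under donor1) carries the recipient's subtree, the second (under
    donor2) is a bare reference.  Reticulation edges are written in the
    ``:length:support:gamma`` style with length 0, empty support and the
    hybridization degree as gamma.  A donor that was itself removed in a
    later event no longer has a node in the tree; such an edge is only
    representable in the TSV export and is omitted here.
    """
    in_tree = set(map(id, net.tree.root.walk()))
    # donor TreeNode id -> list of (hybrid tag, degree, recipient node | None)
    extras: dict[int, list[tuple[str, float, TreeNode | None]]] = {}
    for num, r in enumerate(net.reticulations, start=1):
        tag = f"#H{num}"
        recipient = net.node_index.get(r.recipient, TreeNode(label=r.recipient))
        for donor, degree, payload in (
            (r.donor1, r.degree1, recipient),
            (r.donor2, r.degree2, None),
        ):
            node = net.node_index.get(donor)
            if node is None or id(node) not in in_tree:
                continue
            extras.setdefault(id(node), []).append((tag, degree, payload))

    def render(node: TreeNode, with_length: bool = True) -> str:
        parts = [render(c) for c in node.children]
        for tag, degree, payload in extras.get(id(node), []):
            if payload is not None:
                inner = render(payload, with_length=False)
                parts.append(f"({inner}){tag}:0.0::{degree:.6g}")
            else:
                parts.append(f"{tag}:0.0::{degree:.6g}")
        body = f"({','.join(parts)})" if parts else ""
        label = node.label or ""
        out = body + label if (body or label) else ""
        if with_length and node.length is not None:
            out += f":{_fmt_len(node.length)}"
        return out

    return render(net.tree.root, with_length=False) + ";"


def reticulations_frame(net: HybridizationNetwork):
    """Reticulation records as a pandas DataFrame (one row per event)."""
    import pandas as pd

    rows = []
    for r in net.reticulations:
        rows.append(
            {
                "recipient": r.recipient,
                "donor1": r.donor1,
                "donor1_members": ",".join(r.donor1_members),
                "degree1": r.degree1,
                "donor2": r.donor2,
                "donor2_members": ",".join(r.donor2_members),
                "degree2": r.degree2,
                "score": r.score,
                "step": r.step,
                "round": r.round,
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_reticulations_tsv(net: HybridizationNetwork, path) -> None:
    reticulations_frame(net).to_csv(path, sep="\t", index=False)
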