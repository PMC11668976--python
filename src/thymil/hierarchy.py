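"""Divide-and-conquer classification tree over the five thymoma subtypes.

Morphologically similar subtypes are grouped first: the root separates the
lymphocyte-poor pair {A, B3} from the lymphocyte-rich triple {AB, B1, B2};
a binary node then splits A from B3 and a ternary node splits AB/B1/B2.
Every node carries its own attention-MIL bag classifier (optionally
refined with pseudo-labels) trained only on slides whose label falls in
the node's subsets, with the branch index as the node-local label.

Stage outputs compose into a five-class prediction either by hard routing
(follow the argmax branch to a leaf) or softly (leaf probability =
product of branch probabilities along its path), the latter yielding a
proper distribution usable for macro-AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .mil import Bag, GatedAttentionMIL, IdentityEncoder, LinearEncoder, MILModel, TrainConfig
from .pseudo import RefineResult, refine_loop

__all__ = [
    "HierarchyNode", "build_default_hierarchy", "fit_hierarchy",
    "predict_slide", "predict_cohort", "save_tree", "load_tree",
    "DEFAULT_LABELS",
]

DEFAULT_LABELS = ("A", "AB", "B1", "B2", "B3")

# training-set size the default epoch schedule is calibrated for; smaller
# node training sets stretch the schedule so the optimizer-step budget and
# decay horizon stay comparable
SCHEDULE_REFERENCE_BAGS = 141


@dataclass
class HierarchyNode:
    """One classifier node: ordered branch subsets, a model, child nodes."""

    name: str
    class_subsets: list
    model: RefineResult | None = None
    children: dict = field(default_factory=dict)   # branch index -> node

    def __post_init__(self) -> None:
        flat = [l for sub in self.class_subsets for l in sub]
        if len(flat) != len(set(flat)):
            raise ValueError(f"node {self.name}: branch subsets must be disjoint")

    @property
    def n_branches(self) -> int:
        return len(self.class_subsets)

    def leaves(self) -> list[str]:
        out = []
        for i, sub in enumerate(self.class_subsets):
            if len(sub) == 1:
                out.append(sub[0])
            else:
                out.extend(self.children[i].leaves())
        return out


def build_default_hierarchy() -> HierarchyNode:
    """Root {A,B3} vs {AB,B1,B2}; then A vs B3; then AB vs B1 vs B2."""
    root = HierarchyNode(name="root",
                         class_subsets=[("A", "B3"), ("AB", "B1", "B2")])
    root.children[0] = HierarchyNode(name="A_vs_B3",
                                     class_subsets=[("A",), ("B3",)])
    root.children[1] = HierarchyNode(name="AB_B1_B2",
                                     class_subsets=[("AB",), ("B1",), ("B2",)])
    return root


def _node_selection(node: HierarchyNode, bags, labels):
    """Slides belonging to this node, with branch-index local labels."""
    sel_bags, sel_labels = [], []
    for bag, lab in zip(bags, labels):
        for i, sub in enumerate(node.class_subsets):
            if lab in sub:
                sel_bags.append(bag)
                sel_labels.append(i)
                break
    return sel_bags, sel_labels


def fit_hierarchy(root: HierarchyNode, train_bags, train_labels,
                  val_bags, val_labels, config: TrainConfig,
                  refine: bool = True, n_rounds: int = 3,
                  k: int | None = None, hidden: int = 32,
                  n_restarts: int = 3) -> HierarchyNode:
    """Fit every node's bag classifier on its slice of the cohort.

    ``train_labels``/``val_labels`` are subtype names.  Node-local class
    imbalance (e.g. 21 A vs 83 AB slides) is countered with
    inverse-frequency loss weights.  With ``refine`` the pseudo-label loop
    runs per node; without it the encoder is frozen at the identity and
    each node reduces to plain attention-MIL.

    The per-epoch schedule (batch size 1, lr decayed every fixed number of
    epochs) hands a small training set a much smaller optimisation budget
    than the ~141-bag scale the defaults are calibrated for, and nodes
    deeper in the tree see fewer slides still.  Epoch count, decay interval
    and early-stop patience are therefore scaled per node by
    ``SCHEDULE_REFERENCE_BAGS / node training size``, keeping the budget in
    optimizer steps comparable across nodes and cohort sizes.
    """
    nodes = [root]
    node_idx = 0
    ref_n = SCHEDULE_REFERENCE_BAGS
    while nodes:
        node = nodes.pop()
        tb, tl = _node_selection(node, train_bags, train_labels)
        vb, vl = _node_selection(node, val_bags, val_labels)
        for i in range(node.n_branches):
            if not any(l == i for l in tl):
                raise ValueError(
                    f"node {node.name}: empty training set for branch "
                    f"{node.class_subsets[i]}")
        counts = np.bincount(tl, minlength=node.n_branches).astype(float)
        weights = counts.sum() / (node.n_branches * counts)
        scale = ref_n / len(tb)
        cfg = replace(
            config, seed=config.seed + 1000 * node_idx,
            epochs=int(np.ceil(config.epochs * scale)),
            patch_epochs=int(np.ceil(config.patch_epochs * scale)),
            lr_decay_every=int(np.ceil(config.lr_decay_every * scale)),
            patience=int(np.ceil(config.patience * scale)))
        encoder = None if refine else IdentityEncoder()
        node.model = refine_loop(tb, tl, vb, vl, cfg,
                                 n_rounds=n_rounds if refine else 1,
                                 k=k, class_weights=weights, encoder=encoder,
                                 n_classes=node.n_branches, hidden=hidden,
                                 n_restarts=n_restarts)
        nodes.extend(node.children.values())
        node_idx += 1
    return root


def predict_slide(root: HierarchyNode, bag: Bag, mode: str = "hard",
                  class_labels: tuple = DEFAULT_LABELS):
    """Compose node outputs into a five-class probability vector.

    hard: follow the argmax branch at each node; the reached leaf carries
    the product of traversed branch probabilities, all other classes zero,
    renormalised.  soft: each leaf's probability is the product of branch
    probabilities along its root-to-leaf path (a proper distribution).
    Returns ``(probs, trace)`` where the trace lists each visited node and
    its branch probabilities.
    """
    if mode not in ("hard", "soft"):
        raise ValueError("mode must be 'hard' or 'soft'")
    probs = np.zeros(len(class_labels))
    trace = []

    def node_probs(node):
        if node.model is None:
            raise ValueError(f"node {node.name} is not fitted")
        p, _, _ = node.model.mil.head.forward(node.model.encoder(bag.Z))
        return p

    if mode == "soft":
        def descend(node, mass):
            p = node_probs(node)
            trace.append({"node": node.name, "branch_probs": p.tolist()})
            for i, sub in enumerate(node.class_subsets):
                if len(sub) == 1:
                    probs[class_labels.index(sub[0])] += mass * p[i]
                else:
                    descend(node.children[i], mass * p[i])
        descend(root, 1.0)
    else:
        node, mass = root, 1.0
        while True:
            p = node_probs(node)
            i = int(np.argmax(p))
            trace.append({"node": node.name, "branch_probs": p.tolist(),
                          "chosen": i})
            mass *= p[i]
            sub = node.class_subsets[i]
            if len(sub) == 1:
                probs[class_labels.index(sub[0])] = mass
                break
            node = node.children[i]
    total = probs.sum()
    if total > 0:
        probs = probs / total
    return probs, trace


def predict_cohort(root: HierarchyNode, bags, mode: str = "soft",
                   class_labels: tuple = DEFAULT_LABELS) -> np.ndarray:
    """(n_slides, n_classes) probability matrix over the cohort."""
    return np.vstack([predict_slide(root, b, mode, class_labels)[0]
                      for b in bags])


# ---------------------------------------------------------------------------
# serialisation


def _encoder_state(enc):
    if isinstance(enc, LinearEncoder):
        return {"kind": "linear", "W": enc.W, "b": enc.b}
    if isinstance(enc, IdentityEncoder):
        return {"kind": "identity"}
    raise ValueError(f"cannot serialise encoder {type(enc).__name__}")


def save_tree(root: HierarchyNode, out_dir) -> None:
    """Write the tree spec as JSON plus one npz of weights per node."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def spec(node):
        return {"name": node.name,
                "class_subsets": [list(s) for s in node.class_subsets],
                "children": {str(i): spec(ch) for i, ch in node.children.items()}}

    (out / "tree.json").write_text(json.dumps(spec(root), indent=1))

    def dump(node):
        if node.model is not None:
            arrays = {}
            head = node.model.mil.head
            for k, v in head.params.items():
                arrays[f"head_{k}"] = v
            es = _encoder_state(node.model.encoder)
            arrays["encoder_kind"] = np.array(es["kind"])
            if es["kind"] == "linear":
                arrays["enc_W"] = es["W"]
                arrays["enc_b"] = es["b"]
            arrays["meta"] = np.array([head.in_dim, head.n_classes, head.hidden])
            np.savez(out / f"node_{node.name}.npz", **arrays)
        for ch in node.children.values():
            dump(ch)

    dump(root)


def load_tree(in_dir) -> HierarchyNode:
    src = Path(in_dir)
    spec = json.loads((src / "tree.json").read_text())

    def build(d):
        node = HierarchyNode(name=d["name"],
                             class_subsets=[tuple(s) for s in d["class_subsets"]])
        for i, ch in d["children"].items():
            node.children[int(i)] = build(ch)
        path = src / f"node_{node.name}.npz"
        if path.exists():
            data = np.load(path, allow_pickle=False)
            in_dim, n_classes, hidden = (int(x) for x in data["meta"])
            head = GatedAttentionMIL(in_dim, n_classes, hidden)
            for k in head.params:
                head.params[k] = data[f"head_{k}"]
            if str(data["encoder_kind"]) == "linear":
                enc = LinearEncoder(data["enc_W"].shape[1], data["enc_W"].shape[0])
                enc.W = data["enc_W"]
                enc.b = data["enc_b"]
            else:
                enc = IdentityEncoder()
            node.model = RefineResult(encoder=enc, mil=MILModel(head=head),
                                      patch_classifier=None, history=[],
                                      best_round=0)
        return node

    return build(spec)
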