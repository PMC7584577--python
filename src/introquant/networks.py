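"""Phylogenetic-network summaries and the reticulation proportion test.

A phylogenetic network in extended Newick encodes each hybrid (reticulation)
node by a ``#H<id>`` tag repeated wherever the node re-attaches.  The only
summaries needed here are the number of distinct tip labels and the number
of distinct hybrid tags; the comparison between two genera treats each
genus' reticulation count as successes out of the number of leaf pairs
(n choose 2 — the number of species pairs that could in principle have
hybridized) and applies a two-proportion chi-square test with Yates
continuity correction, one- or two-sided, with the matching Wald confidence
interval for the difference in proportions.  Candidate networks fitted with
different numbers of reticulations are ranked by AIC computed from their
log pseudo-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "NetworkSummary",
    "PropTestResult",
    "ParseError",
    "parse_enewick",
    "prop_test",
    "reticulation_comparison",
    "aic_rank",
    "random_enewick",
]


class ParseError(ValueError):
    def __init__(self, msg: str, position: int) -> None:
        super().__init__(f"{msg} at position {position}")
        self.position = position


@dataclass(frozen=True)
class NetworkSummary:
    name: str
    n_leaves: int
    n_reticulations: int

    @property
    def n_pairs(self) -> int:
        return self.n_leaves * (self.n_leaves - 1) // 2


@dataclass(frozen=True)
class PropTestResult:
    chi2: float
    df: int
    p: float
    alternative: str
    estimate: tuple[float, float]
    conf_int: tuple[float, float]
    continuity: bool

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "alternative": self.alternative,
            "estimate": list(self.estimate),
            "conf_int": list(self.conf_int),
            "continuity": self.continuity,
        }


_LABEL_END = set("(),;:")


def parse_enewick(text: str, name: str = "network") -> NetworkSummary:
    """Count distinct leaves and reticulations in an extended-Newick string.

    A tip whose label carries a ``#H`` tag is an occurrence of a hybrid node,
    not a regular leaf; every distinct ``#H`` tag counts as one reticulation
    no matter how often it appears.  Branch lengths are accepted and ignored.
    """
    s = text.strip()
    if not s:
        raise ParseError("empty network string", 0)
    pos = 0
    leaves: set[str] = set()
    hybrids: set[str] = set()

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_END:
            pos += 1
        return s[start:pos].strip()

    def read_branch_length() -> None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in _LABEL_END:
                pos += 1
            try:
                float(s[start:pos])
            except ValueError:
                raise ParseError(f"bad branch length {s[start:pos]!r}", start) from None

    def record(label: str, is_tip: bool, at: int) -> None:
        if "#" in label:
            tag = label[label.index("#") :]
            if not tag.startswith("#"):  # pragma: no cover - defensive
                raise ParseError(f"bad hybrid tag {tag!r}", at)
            hybrids.add(tag)
        elif is_tip:
            if not label:
                raise ParseError("unlabeled tip", at)
            leaves.add(label)

    def subtree() -> None:
        nonlocal pos
        skip_ws()
        if pos >= len(s):
            raise ParseError("unexpected end of input", pos)
        if s[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                subtree()
                skip_ws()
                if pos >= len(s):
                    raise ParseError("unbalanced parentheses", open_at)
                if s[pos] == ",":
                    pos += 1
                    skip_ws()
                    if pos < len(s) and s[pos] in "),":
                        raise ParseError("dangling comma", pos)
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                if s[pos] == ";":
                    raise ParseError("unbalanced parentheses", open_at)
                raise ParseError(f"unexpected character {s[pos]!r}", pos)
            label_at = pos
            label = read_label()
            record(label, is_tip=False, at=label_at)
            read_branch_length()
        else:
            label_at = pos
            label = read_label()
            if not label:
                raise ParseError(f"unexpected character {s[pos]!r}", pos)
            record(label, is_tip=True, at=label_at)
            read_branch_length()

    subtree()
    skip_ws()
    if pos >= len(s) or s[pos] != ";":
        raise ParseError("missing terminating ';'", pos)
    pos += 1
    skip_ws()
    if pos != len(s):
        raise ParseError("trailing characters after ';'", pos)
    return NetworkSummary(name=name, n_leaves=len(leaves), n_reticulations=len(hybrids))


def prop_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alternative: str = "two_sided",
    continuity: bool = True,
    conf_level: float = 0.95,
) -> PropTestResult:
    """Two-sample test for equality of proportions (chi-square, df = 1).

    The statistic comes from the 2x2 table [[x1, n1-x1], [x2, n2-x2]]; with
    ``continuity`` each |observed - expected| is reduced by min(0.5, |O-E|)
    (Yates, capped so near-null tables cannot go negative).  The confidence
    interval for p1 - p2 is the Wald interval, widened by 0.5(1/n1 + 1/n2)
    under continuity, clamped to [-1, 1]; one-sided intervals pin the
    unbounded end at +-1.  One-sided p halves the chi-square tail when the
    observed difference matches the alternative's direction.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")

    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected == 0).any():
        chi2 = 0.0
    else:
        dev = np.abs(obs - expected)
        if continuity:
            dev = dev - np.minimum(0.5, dev)
        chi2 = float((dev**2 / expected).sum())

    p1, p2 = x1 / n1, x2 / n2
    delta = p1 - p2
    tail = float(scipy.stats.chi2.sf(chi2, df=1))
    if alternative == "two_sided":
        p = tail
    else:
        matches = delta > 0 if alternative == "greater" else delta < 0
        half = tail / 2.0
        p = half if (matches or delta == 0) else 1.0 - half
        if delta == 0:
            p = 0.5 if chi2 == 0 else half

    se = float(np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2))
    corr = 0.5 * (1 / n1 + 1 / n2) if continuity else 0.0
    if alternative == "two_sided":
        z = scipy.stats.norm.ppf(0.5 + conf_level / 2)
        lo, hi = delta - (z * se + corr), delta + (z * se + corr)
    elif alternative == "greater":
        z = scipy.stats.norm.ppf(conf_level)
        lo, hi = delta - (z * se + corr), 1.0
    else:
        z = scipy.stats.norm.ppf(conf_level)
        lo, hi = -1.0, delta + (z * se + corr)
    lo, hi = max(lo, -1.0), min(hi, 1.0)
    return PropTestResult(
        chi2=chi2,
        df=1,
        p=float(p),
        alternative=alternative,
        estimate=(p1, p2),
        conf_int=(float(lo), float(hi)),
        continuity=continuity,
    )


def reticulation_comparison(
    summary1: NetworkSummary,
    summary2: NetworkSummary,
    alternative: str = "two_sided",
    continuity: bool = True,
) -> PropTestResult:
    """Compare two genera's reticulation counts relative to their numbers of
    leaf pairs (reticulations as successes out of n-choose-2 trials)."""
    for s in (summary1, summary2):
        if s.n_reticulations > s.n_pairs:
            raise ValueError(
                f"{s.name}: {s.n_reticulations} reticulations exceed {s.n_pairs} leaf pairs"
            )
    return prop_test(
        summary1.n_reticulations,
        summary1.n_pairs,
        summary2.n_reticulations,
        summary2.n_pairs,
        alternative=alternative,
        continuity=continuity,
    )


def aic_rank(candidates) -> list[dict]:
    """Rank candidate networks by AIC = 2k - 2 log(pseudo-likelihood).

    ``candidates`` iterates (n_reticulations, log_pseudo_likelihood,
    n_parameters); ties in AIC go to the network with fewer reticulations.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidate networks to rank")
    rows = [
        {
            "n_reticulations": int(r),
            "log_pseudo_likelihood": float(ll),
            "n_parameters": int(k),
            "aic": 2.0 * k - 2.0 * ll,
        }
        for r, ll, k in cands
    ]
    return sorted(rows, key=lambda d: (d["aic"], d["n_reticulations"]))


def random_enewick(
    n_leaves: int, n_reticulations: int, rng: np.random.Generator
) -> tuple[str, NetworkSummary]:
    """Emit a random extended-Newick network with known summary counts.

    Builds a random binary tree over T1..Tn, then for each reticulation
    wraps a random leaf occurrence as ``(leaf)#Hi`` and re-attaches ``#Hi``
    as an extra child of a random other internal node.  Used as the
    round-trip oracle for the parser.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    labels = [f"T{i + 1}" for i in range(n_leaves)]
    # nested-list tree: a node is [tag, child, child, ...]; tag "" = plain
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(int(v) for v in rng.choice(len(nodes), size=2, replace=False))
        merged = ["", nodes[i], nodes[j]]
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)] + [merged]
    root = nodes[0] if isinstance(nodes[0], list) else ["", nodes[0]]

    def walk(node, acc):
        if isinstance(node, list):
            acc.append(node)
            for ch in node[1:]:
                walk(ch, acc)
        return acc

    for h in range(1, n_reticulations + 1):
        # wrap a random plain-leaf occurrence under a tagged hybrid node
        internals = walk(root, [])
        slots = [
            (nd, t)
            for nd in internals
            for t, ch in enumerate(nd)
            if t > 0 and isinstance(ch, str) and not ch.startswith("#")
        ]
        nd, t = slots[int(rng.integers(len(slots)))]
        wrapped = [f"#H{h}", nd[t]]
        nd[t] = wrapped
        # re-attach the hybrid tag elsewhere
        others = [x for x in walk(root, []) if x is not wrapped]
        others[int(rng.integers(len(others)))].append(f"#H{h}")

    def serialize(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(serialize(ch) for ch in node[1:]) + ")" + node[0]

    text = serialize(root) + ";"
    return text, NetworkSummary("random", n_leaves, n_reticulations)
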