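"""Scale definitions and the 37-node map for the psychosocial network.

Seven self-report instruments contribute 58 raw items:

* PHQ-9 (depression, 9 items, 0-3)
* GAD-7 (anxiety, 7 items, 0-3)
* UCLA-3 (loneliness, 3 items, 1-3)
* RSES (self-esteem, 10 items, 0-3; five negatively worded items reverse-scored)
* MSPSS (perceived social support, 12 items, 1-7; three 4-item subscales)
* SOI-R (sociosexual orientation, 9 items, 1-5; item 6 reverse-scored;
  only the attitude and desire facets enter the network)
* SIHS (internalized homonegativity, 8 items, 1-7; three subscales,
  higher = greater acceptance of one's sexual orientation)

Network nodes are the 29 individual items of PHQ-9/GAD-7/UCLA-3/RSES plus the
8 subscale scores of MSPSS (3), SOI-R attitude/desire (2) and SIHS (3),
for 37 nodes in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Scale:
    """One questionnaire: its columns, response range and node rule.

    Parameters
    ----------
    name : short scale identifier (e.g. ``"PHQ"``).
    items : ordered raw-data column names.
    item_range : inclusive integer (min, max) of valid responses.
    reverse_items : items whose raw response r is re-coded to
        ``min + max - r`` before scoring (negatively worded items).
    node_rule : ``"item"`` (each item is a network node) or ``"subscale"``
        (subscale scores are nodes).
    subscales : subscale name -> ordered member items (node_rule="subscale").
    subscale_score : ``"sum"`` or ``"mean"`` of member items.
    total_score : how the scale total is formed (``"sum"`` everywhere except
        MSPSS/SOI-R, which report subscale scores only).
    """

    name: str
    items: tuple[str, ...]
    item_range: tuple[int, int]
    reverse_items: tuple[str, ...] = ()
    node_rule: str = "item"
    subscales: dict[str, tuple[str, ...]] = field(default_factory=dict)
    subscale_score: str = "sum"
    total_score: str = "sum"

    def __post_init__(self):
        if self.node_rule not in ("item", "subscale", "none"):
            raise ValueError(f"unknown node_rule {self.node_rule!r}")
        if self.item_range[0] >= self.item_range[1]:
            raise ValueError(f"{self.name}: degenerate item range {self.item_range}")
        seen = set()
        for it in self.items:
            if it in seen:
                raise ValueError(f"{self.name}: duplicated item {it}")
            seen.add(it)
        for rev in self.reverse_items:
            if rev not in seen:
                raise ValueError(f"{self.name}: reverse item {rev} not in items")
        if self.node_rule == "subscale":
            members = [m for ms in self.subscales.values() for m in ms]
            if len(members) != len(set(members)):
                raise ValueError(f"{self.name}: item in more than one subscale")
            for m in members:
                if m not in seen:
                    raise ValueError(f"{self.name}: subscale member {m} unknown")

    def reverse(self, item: str, value):
        """Re-code a reverse-keyed response onto the aligned direction."""
        lo, hi = self.item_range
        return lo + hi - value


def _items(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(1, n + 1))


#: Short glosses for the item nodes (used as human-readable labels).
ITEM_GLOSSES: dict[str, str] = {
    "PHQ1": "anhedonia",
    "PHQ2": "sad mood",
    "PHQ3": "sleep problems",
    "PHQ4": "feeling tired",
    "PHQ5": "appetite problems",
    "PHQ6": "feeling guilty",
    "PHQ7": "trouble concentrating",
    "PHQ8": "psychomotor symptoms",
    "PHQ9": "suicidal thoughts",
    "GAD1": "feeling nervous",
    "GAD2": "cannot stop worrying",
    "GAD3": "worrying too much",
    "GAD4": "trouble relaxing",
    "GAD5": "restless",
    "GAD6": "irritable",
    "GAD7": "feeling afraid",
    "UCLA1": "lacking companionship",
    "UCLA2": "feeling left out",
    "UCLA3": "feeling isolated",
    "RSES1": "worth",
    "RSES2": "good qualities",
    "RSES3": "failure",
    "RSES4": "doing things well",
    "RSES5": "proud",
    "RSES6": "positive attitude",
    "RSES7": "satisfied with myself",
    "RSES8": "respect for myself",
    "RSES9": "feeling useless",
    "RSES10": "no good",
    "MSPSS_FAM": "family support",
    "MSPSS_FRI": "friends support",
    "MSPSS_SO": "significant other support",
    "SOI_ATT": "sociosexual attitude",
    "SOI_DES": "sociosexual desire",
    "SIHS_SC": "social comfort with gay men",
    "SIHS_PUBID": "public identification as gay",
    "SIHS_PC": "personal comfort with gay identity",
}

# RSES negatively worded items (reverse-scored): failure, not much to be
# proud of, wish more respect for myself, feeling useless, no good at all.
_RSES_REVERSE = ("RSES3", "RSES5", "RSES8", "RSES9", "RSES10")


def default_scales() -> dict[str, Scale]:
    """The seven study scales with their standard scoring conventions."""
    return {
        "PHQ": Scale("PHQ", _items("PHQ", 9), (0, 3)),
        "GAD": Scale("GAD", _items("GAD", 7), (0, 3)),
        "UCLA": Scale("UCLA", _items("UCLA", 3), (1, 3)),
        "RSES": Scale("RSES", _items("RSES", 10), (0, 3), reverse_items=_RSES_REVERSE),
        "MSPSS": Scale(
            "MSPSS",
            _items("MSPSS", 12),
            (1, 7),
            node_rule="subscale",
            subscales={
                "MSPSS_FAM": ("MSPSS3", "MSPSS4", "MSPSS8", "MSPSS11"),
                "MSPSS_FRI": ("MSPSS6", "MSPSS7", "MSPSS9", "MSPSS12"),
                "MSPSS_SO": ("MSPSS1", "MSPSS2", "MSPSS5", "MSPSS10"),
            },
            subscale_score="mean",
            total_score="none",
        ),
        "SOI": Scale(
            "SOI",
            _items("SOI", 9),
            (1, 5),
            reverse_items=("SOI6",),
            node_rule="subscale",
            subscales={
                # behavior facet (SOI1-3) is deliberately NOT a node: it
                # overlaps with the risk-behavior outcome.
                "SOI_ATT": ("SOI4", "SOI5", "SOI6"),
                "SOI_DES": ("SOI7", "SOI8", "SOI9"),
            },
            subscale_score="mean",
            total_score="none",
        ),
        "SIHS": Scale(
            "SIHS",
            _items("SIHS", 8),
            (1, 7),
            node_rule="subscale",
            subscales={
                "SIHS_SC": ("SIHS1", "SIHS2", "SIHS3"),
                "SIHS_PUBID": ("SIHS4", "SIHS5"),
                "SIHS_PC": ("SIHS6", "SIHS7", "SIHS8"),
            },
            subscale_score="sum",
            total_score="none",
        ),
    }


@dataclass(frozen=True)
class ScaleMap:
    """Full column map: scales, demographics and behavior items."""

    scales: dict[str, Scale] = field(default_factory=default_scales)
    id_column: str = "participant_id"
    age_column: str = "age"
    demographic_columns: tuple[str, ...] = (
        "marital_status",
        "education",
        "sexual_orientation",
    )
    condom_column: str = "condom_use"
    partner_column: str = "partner_count"

    def __post_init__(self):
        labels = self.node_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicated node labels")
        if len(labels) != 37:
            raise ValueError(f"node rules yield {len(labels)} nodes, expected 37")
        cols = self.item_columns()
        if len(cols) != len(set(cols)):
            raise ValueError("a column is named by more than one scale")

    def item_columns(self) -> list[str]:
        return [c for s in self.scales.values() for c in s.items]

    def node_labels(self) -> list[str]:
        out: list[str] = []
        for s in self.scales.values():
            if s.node_rule == "item":
                out.extend(s.items)
            elif s.node_rule == "subscale":
                out.extend(s.subscales.keys())
        return out

    def node_construct(self) -> dict[str, str]:
        """Node label -> scale (construct) of origin."""
        out: dict[str, str] = {}
        for s in self.scales.values():
            if s.node_rule == "item":
                for c in s.items:
                    out[c] = s.name
            elif s.node_rule == "subscale":
                for sub in s.subscales:
                    out[sub] = s.name
        return out

    def behavior_columns(self) -> list[str]:
        return [self.condom_column, self.partner_column]

    def key_columns(self) -> list[str]:
        """Default 'key variables' for listwise deletion: all items, both
        behavior codes, and age (the network and linkage inputs)."""
        return self.item_columns() + self.behavior_columns() + [self.age_column]


DEFAULT_SCALE_MAP = ScaleMap()

#: Node labels in canonical (reporting) order.
NODE_LABELS: list[str] = DEFAULT_SCALE_MAP.node_labels()
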