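"""Resistance-mechanism decision logic.

Per experiment, genes are partitioned into up-regulated (U), down-
regulated (D), and unchanged (S) sets; named intersections across the
dose pairs at 4 h ('1' vs '3') and 72 h ('4' vs '5') are formed; and a
rule table translates (gene set, enriched functional category) into a
verdict on whether the cells' resistance to glucocorticoid-induced
apoptosis is inherent (present before treatment) or acquired
(developed under exposure).

F_p marks apoptosis evasion / cell-cycle progression functions, F_a
apoptosis induction / cell-cycle arrest.  A set with no enriched
category yields 'undefined'; an empty gene set is 'not_applicable'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ExperimentSets",
    "Verdict",
    "build_sets",
    "intersect_sets",
    "classify_resistance",
    "map_cluster_to_set",
    "load_rules",
    "DEFAULT_RULES",
    "INTERSECTION_LABELS",
]

INTERSECTION_LABELS = (
    "S1∩S3",
    "U1∩U3",
    "D1∩D3",
    "U1∩D3",
    "D1∩U3",
    "S4∩S5",
    "U4∩U5",
    "D4∩D5",
    "U4∩D5",
    "D4∩U5",
)

# (set label) -> {category: verdict}; 'qualified' verdicts carry '~'.
DEFAULT_RULES: dict[str, dict[str, str]] = {
    # 4 h intersections (early response, low vs high dose)
    "S1∩S3": {"F_p": "acquired", "F_a": "inherent"},
    "U1∩U3": {"F_p": "inherent", "F_a": "acquired"},
    "D1∩D3": {"F_p": "acquired", "F_a": "inherent"},
    "U1∩D3": {"F_p": "acquired", "F_a": "inherent"},
    "D1∩U3": {"F_p": "inherent", "F_a": "acquired"},
    # 72 h intersections (late response)
    "S4∩S5": {"F_p": "acquired", "F_a": "undefined"},
    "U4∩U5": {"F_p": "acquired", "F_a": "undefined"},
    "D4∩D5": {"F_p": "undefined", "F_a": "inherent"},
    "U4∩D5": {"F_p": "acquired", "F_a": "undefined"},
    "D4∩U5": {"F_p": "acquired", "F_a": "undefined"},
    # individual 4 h sets
    "U1": {"F_p": "inherent", "F_a": "acquired"},
    "U2": {"F_p": "inherent", "F_a": "acquired"},
    "U3": {"F_p": "inherent", "F_a": "acquired"},
    "D1": {"F_p": "acquired", "F_a": "inherent"},
    "D2": {"F_p": "acquired", "F_a": "inherent"},
    "D3": {"F_p": "acquired", "F_a": "inherent"},
    # individual 72 h sets
    "U4": {"F_p": "acquired", "F_a": "undefined"},
    "U5": {"F_p": "acquired", "F_a": "undefined"},
    "D4": {"F_p": "acquired", "F_a": "~inherent"},
    "D5": {"F_p": "acquired", "F_a": "~inherent"},
}


@dataclass
class ExperimentSets:
    """Disjoint U/D/S partition of the CGS for one experiment."""

    experiment_id: str
    S: set
    U: set
    D: set

    def __post_init__(self) -> None:
        if self.S & self.U or self.S & self.D or self.U & self.D:
            raise ValueError("S, U, D must be pairwise disjoint")

    @property
    def universe(self) -> set:
        return self.S | self.U | self.D

    def __getitem__(self, label: str) -> set:
        return {"S": self.S, "U": self.U, "D": self.D}[label]


@dataclass
class Verdict:
    """Resistance classification of one gene set."""

    set_label: str
    categories_present: frozenset
    resistance: str  # inherent | acquired | undefined | not_applicable
    qualified: bool = False
    sub_verdicts: dict = field(default_factory=dict)
    genes: tuple = ()
    rule: str = ""


def build_sets(labeling) -> ExperimentSets:
    """Partition genes of one experiment's DE labelling into U/D/S."""
    sets = labeling.sets()
    return ExperimentSets(
        experiment_id=labeling.experiment_id,
        S=sets["S"],
        U=sets["U"],
        D=sets["D"],
    )


def intersect_sets(sets_by_exp: dict[str, ExperimentSets]) -> dict[str, set]:
    """The ten named dose-pair intersections at 4 h and 72 h."""
    required = {"1", "3", "4", "5"}
    missing = required - set(sets_by_exp)
    if missing:
        raise ValueError(f"experiments missing for intersections: {sorted(missing)}")
    out = {}
    for label in INTERSECTION_LABELS:
        left, right = label.split("∩")
        a = sets_by_exp[left[1]][left[0]]
        b = sets_by_exp[right[1]][right[0]]
        out[label] = a & b
    return out


def classify_resistance(
    set_label: str,
    category_present,
    genes=None,
    rules: dict[str, dict[str, str]] | None = None,
) -> Verdict:
    """Apply the verdict rule table to one gene set.

    ``category_present`` holds the functional categories enriched at
    the chosen significance level (only F_p/F_a carry verdict rules;
    extra categories such as F_m/F_i are reported but not ruled on).
    No relevant category -> 'undefined'; both -> both sub-verdicts are
    reported under an overall 'undefined' (mixed) call; an explicitly
    empty gene set -> 'not_applicable'.
    """
    rules = DEFAULT_RULES if rules is None else rules
    if set_label not in rules:
        raise ValueError(
            f"unknown set label {set_label!r}; known: {sorted(rules)}"
        )
    cats = frozenset(category_present)
    gene_tuple = tuple(sorted(genes)) if genes is not None else ()
    if genes is not None and len(gene_tuple) == 0:
        return Verdict(set_label, cats, "not_applicable", rule="empty set")
    ruled = {c: rules[set_label][c] for c in ("F_p", "F_a") if c in cats}

    def _strip(v: str) -> tuple[str, bool]:
        return (v[1:], True) if v.startswith("~") else (v, False)

    if not ruled:
        return Verdict(
            set_label, cats, "undefined", genes=gene_tuple, rule="no category fired"
        )
    if len(ruled) == 1:
        (cat, verdict), = ruled.items()
        v, q = _strip(verdict)
        return Verdict(
            set_label, cats, v, qualified=q, genes=gene_tuple,
            rule=f"{set_label} & {cat}",
        )
    subs = {c: _strip(v)[0] for c, v in ruled.items()}
    return Verdict(
        set_label,
        cats,
        "undefined",
        sub_verdicts=subs,
        genes=gene_tuple,
        rule=f"{set_label} mixed F_p/F_a",
    )


def load_rules(path) -> dict[str, dict[str, str]]:
    """Read an override rule table: TSV with columns set_label,
    category, verdict (verdicts may carry a leading '~' for qualified
    calls).  Labels absent from the file fall back to the defaults."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"set_label", "category", "verdict"}
    if not need <= set(df.columns):
        raise ValueError(f"rules table needs columns {sorted(need)}")
    rules = {k: dict(v) for k, v in DEFAULT_RULES.items()}
    for _, row in df.iterrows():
        rules.setdefault(row["set_label"], {})[row["category"]] = row["verdict"]
    return rules


def map_cluster_to_set(
    cluster_mean_by_exp: dict[str, float],
    threshold_by_exp: dict[str, float],
) -> str:
    """Composite behavioural label of a cluster mean profile.

    Each experiment's cluster mean M is thresholded against that
    experiment's DE scale (z_crit times the median local SD): above ->
    U, below the negative -> D, else S.  Experiments where the cluster
    departs from S name the label (e.g. '~D5'); a flat cluster is
    '~S all'.
    """
    parts = []
    for exp in sorted(cluster_mean_by_exp):
        m = cluster_mean_by_exp[exp]
        thr = threshold_by_exp[exp]
        if m >= thr:
            parts.append(("U", exp))
        elif m <= -thr:
            parts.append(("D", exp))
    if not parts:
        return "~S all"
    return "~" + "+".join(f"{lab}{exp}" for lab, exp in parts)
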