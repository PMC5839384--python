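"""Temperature- and diet-response classification from pairwise contrast calls.

The temperature classifier works, per diet, on the three pairwise contrasts
25v15, 25v20 and 20v15 (higher temperature is always the numerator).  With
``up(15v25)`` meaning the down-call of 25v15, genes are partitioned as:

* ``exclusively_hot`` — up(25v15) and up(25v20), NOT significant in 20v15:
  genes that hold their level at 15 and 20 degC but switch on at 25 degC.
* ``false_hot`` — up(25v15) but not up(25v20): not a hot response at all,
  these genes are really down-regulated at 15 degC.
* ``exclusively_cold`` — up(15v25) and up(15v20), NOT significant in 25v20:
  genes that switch on only at 15 degC.
* ``false_cold`` — up(15v25) but not up(15v20): really down-regulated at
  25 degC.
* ``other`` — everything else.

The diet classifier calls a gene ``ecoli_up``/``bsubtilis_up`` only when the
diet contrast is significant in that direction at ALL three temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ContrastCallSet",
    "TemperatureClassification",
    "classify_temperature_response",
    "classify_diet_response",
    "intersect_across_diets",
    "TEMPERATURE_LABELS",
]

TEMPERATURE_LABELS = ("exclusively_hot", "false_hot", "exclusively_cold", "false_cold", "other")

_CONTRAST_KEYS = ("25v15", "25v20", "20v15")


@dataclass
class ContrastCallSet:
    """Consensus (up, down) gene sets for the three temperature contrasts of one diet.

    Keys are ``25v15``, ``25v20``, ``20v15``; for each, ``up`` holds genes
    higher at the first (warmer) temperature, ``down`` genes higher at the
    second.  Within a contrast a gene cannot be both.
    """

    diet: str
    calls: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(_CONTRAST_KEYS) - set(self.calls)
        if missing:
            raise ValueError(f"missing contrast(s): {sorted(missing)}")
        for key in _CONTRAST_KEYS:
            up, down = self.calls[key]
            clash = set(up) & set(down)
            if clash:
                raise ValueError(
                    f"contradictory call set: gene(s) {sorted(clash)[:5]} both up and "
                    f"down in contrast {key}"
                )
            self.calls[key] = (set(up), set(down))

    def up(self, key: str) -> set[str]:
        return self.calls[key][0]

    def down(self, key: str) -> set[str]:
        return self.calls[key][1]

    def significant(self, key: str) -> set[str]:
        up, down = self.calls[key]
        return up | down


@dataclass
class TemperatureClassification:
    """Output of the temperature classifier for one diet."""

    diet: str
    labels: dict[str, str]  # gene -> label (genes labelled 'other' may be absent)
    both_hot_candidates: set[str]
    both_cold_candidates: set[str]
    #: false_hot genes that are additionally down at 15 vs 20 degC — the
    #: annotation supporting their reading as 15 degC down-regulation
    false_hot_down_at_15v20: set[str]
    false_cold_down_at_25v20: set[str]

    def genes(self, label: str) -> set[str]:
        if label not in TEMPERATURE_LABELS:
            raise ValueError(f"unknown label {label!r}")
        return {g for g, lab in self.labels.items() if lab == label}

    def counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in TEMPERATURE_LABELS if lab != "other"}
        for lab in self.labels.values():
            if lab in out:
                out[lab] += 1
        return out


def classify_temperature_response(calls: ContrastCallSet) -> TemperatureClassification:
    """Partition genes of one diet into the four temperature-response classes.

    Hot side: candidates up in both 25v15 and 25v20 are ``exclusively_hot``
    unless the 20v15 contrast is significant for them (their 15-vs-20 level
    moved, so the response is not exclusive to 25 degC); genes up in 25v15
    but not in 25v20 are ``false_hot``.  The cold side mirrors this with
    the directions reversed.  Candidate sets are kept for reporting: the
    identity ``|up(25v15)| = |candidates| + |false_hot|`` holds by
    construction.
    """
    up_25v15 = calls.up("25v15")
    up_15v25 = calls.down("25v15")
    up_25v20 = calls.up("25v20")
    up_15v20 = calls.down("20v15")

    both_hot = up_25v15 & up_25v20
    exclusively_hot = both_hot - calls.significant("20v15")
    false_hot = up_25v15 - up_25v20

    both_cold = up_15v25 & up_15v20
    exclusively_cold = both_cold - calls.significant("25v20")
    false_cold = up_15v25 - up_15v20

    labels: dict[str, str] = {}
    for lab, genes in (
        ("exclusively_hot", exclusively_hot),
        ("false_hot", false_hot),
        ("exclusively_cold", exclusively_cold),
        ("false_cold", false_cold),
    ):
        for g in genes:
            if g in labels:  # impossible by construction; guard stays
                raise AssertionError(f"gene {g} assigned twice ({labels[g]}, {lab})")
            labels[g] = lab

    return TemperatureClassification(
        diet=calls.diet,
        labels=labels,
        both_hot_candidates=both_hot,
        both_cold_candidates=both_cold,
        false_hot_down_at_15v20=false_hot & calls.up("20v15"),
        false_cold_down_at_25v20=false_cold & calls.down("25v20"),
    )


def classify_diet_response(
    calls_per_temperature: dict[int, tuple[set[str], set[str]]],
) -> pd.Series:
    """Label genes by a diet response consistent across all three temperatures.

    ``calls_per_temperature`` maps temperature -> (genes up on E. coli,
    genes up on B. subtilis) from the between-diet consensus contrast at
    that temperature.  A gene is ``ecoli_up`` only if up on the E. coli
    side at 15, 20 AND 25 degC (``bsubtilis_up`` symmetric); everything
    else is ``none``.
    """
    missing = {15, 20, 25} - set(calls_per_temperature)
    if missing:
        raise ValueError(f"missing temperature key(s): {sorted(missing)}")
    ecoli_sets = [set(calls_per_temperature[t][0]) for t in (15, 20, 25)]
    bsub_sets = [set(calls_per_temperature[t][1]) for t in (15, 20, 25)]
    ecoli_up = set.intersection(*ecoli_sets)
    bsub_up = set.intersection(*bsub_sets)
    clash = ecoli_up & bsub_up
    if clash:  # would require a gene up in both directions of one contrast
        raise ValueError(f"gene(s) {sorted(clash)[:5]} up on both diets")
    labels = {g: "ecoli_up" for g in ecoli_up}
    labels.update({g: "bsubtilis_up" for g in bsub_up})
    universe = set.union(*ecoli_sets, *bsub_sets)
    out = {g: labels.get(g, "none") for g in sorted(universe)}
    return pd.Series(out, name="diet_response", dtype=object)


def intersect_across_diets(
    labels_ecoli: TemperatureClassification,
    labels_bsub: TemperatureClassification,
    label: str,
) -> tuple[set[str], int, int]:
    """Genes carrying ``label`` under both diets, with the two set sizes.

    Returns ``(common_genes, n_ecoli, n_bsub)`` — the (k, n1, n2) triple fed
    to the overlap statistics.
    """
    a = labels_ecoli.genes(label)
    b = labels_bsub.genes(label)
    return a & b, len(a), len(b)
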