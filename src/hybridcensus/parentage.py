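"""Parentage inference: sire/dam identity and F1 vs. BC1 classification.

The model combines three censuses:

* nuclear best-hit census -> the two parent species (the top-2 rows);
* mitochondrial census -> the dam (maternal parent), requiring a near-
  unanimous mito assignment to one of the two parents;
* gene-tree sister census -> a concordance check (the top sister species
  should be among the parents).

Generation is classified from the parent-assigned read counts (c1, c2)
with exact two-sided binomial tests of the dam-parent share against the
F1 expectation p = 1/2 and the two first-generation-backcross (BC1)
expectations p = 3/4 and p = 1/4.  An F1 carries one full haplotype from
each parent (expected 50/50 ancestry); a BC1 is an F1 crossed back to one
parent (expected 75/25).

Because reads are not independent ancestry observations (a backcross
genome carries ancestry in large recombination blocks, so the realized
parental share varies around 75% far more than binomial sampling at the
read count suggests), :class:`ParentageModel` downsamples the counts to an
effective sample size before testing (``n_eff``, default 150, roughly the
number of independent genomic segments at the default simulation scale);
:func:`classify_generation` itself operates on the counts it is given.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

from scipy.stats import binomtest

from .hitcensus import HitCensus
from .treecensus import SisterCensus

F1_SHARE = 0.5
BC1_SHARE = 0.75


@dataclass
class GenerationStats:
    """Binomial test statistics behind a generation call."""

    c1: int
    c2: int
    n_effective: int
    p_hat: float
    p_value_f1: float  # H0: p = 0.5
    p_value_bc1_parent1: float  # H0: p = 0.75
    p_value_bc1_parent2: float  # H0: p = 0.25
    alpha: float


def classify_generation(
    c1: int,
    c2: int,
    alpha: float = 0.001,
    n_max: int | None = None,
) -> tuple[str, GenerationStats]:
    """Classify F1 vs. BC1 from the two parent-assigned read counts.

    ``c1`` is the dam-parent count by convention.  Exact two-sided
    binomial tests are run against p = 1/2 (F1) and p = 3/4, 1/4 (BC1
    toward parent 1 / parent 2).  The call is ``"F1"`` when the F1 model
    is retained and both BC1 models rejected at ``alpha``;
    ``"BC1_toward_parent1"``/``"BC1_toward_parent2"`` when the matching
    BC1 model is retained and the F1 model rejected; otherwise
    ``"ambiguous"``.  ``n_max`` proportionally downsamples the counts
    before testing (effective-sample-size correction).
    """
    n = c1 + c2
    if n <= 0:
        raise ValueError("c1 + c2 must be positive")
    if n_max is not None and n > n_max:
        c1_eff = round(c1 * n_max / n)
        c2_eff = n_max - c1_eff
    else:
        c1_eff, c2_eff = c1, c2
    n_eff = c1_eff + c2_eff
    p05 = binomtest(c1_eff, n_eff, F1_SHARE).pvalue
    p75 = binomtest(c1_eff, n_eff, BC1_SHARE).pvalue
    p25 = binomtest(c1_eff, n_eff, 1.0 - BC1_SHARE).pvalue
    if p05 >= alpha and p75 < alpha and p25 < alpha:
        generation = "F1"
    elif p75 >= alpha and p05 < alpha:
        generation = "BC1_toward_parent1"
    elif p25 >= alpha and p05 < alpha:
        generation = "BC1_toward_parent2"
    else:
        generation = "ambiguous"
    stats = GenerationStats(
        c1=c1,
        c2=c2,
        n_effective=n_eff,
        p_hat=c1 / n,
        p_value_f1=p05,
        p_value_bc1_parent1=p75,
        p_value_bc1_parent2=p25,
        alpha=alpha,
    )
    return generation, stats


def identify_parents(nuclear: HitCensus) -> tuple[str, str]:
    """The two species with the highest unique-best-hit counts.

    Ties are broken lexicographically with a warning.  Requires at least
    two species with nonzero counts.
    """
    nonzero = [(sp, c) for sp, c in nuclear.counts.items() if c > 0]
    if len(nonzero) < 2:
        raise ValueError("need at least two species with nonzero hit counts")
    ranked = sorted(nonzero, key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 2 and ranked[1][1] == ranked[2][1]:
        warnings.warn(
            f"tie for second place between {ranked[1][0]!r} and {ranked[2][0]!r}; "
            "resolved lexicographically",
            stacklevel=2,
        )
    return ranked[0][0], ranked[1][0]


def assign_dam(
    mito: HitCensus, parents: tuple[str, str], threshold: float = 0.99
) -> str:
    """Dam = the mito census top species, if near-unanimous and a parent.

    Returns ``"ambiguous"`` when the mito census is empty, the top species
    falls below ``threshold``, or it is not one of the two parents.
    """
    if mito.n_assigned == 0:
        warnings.warn("empty mitochondrial census; dam is ambiguous", stacklevel=2)
        return "ambiguous"
    props = mito.proportions
    top = max(props, key=lambda sp: (props[sp], sp))
    if props[top] < threshold or top not in parents:
        return "ambiguous"
    return top


@dataclass
class ParentageResults:
    """Fitted parentage call with its test statistics.

    Produced by :meth:`ParentageModel.fit`; ``generation`` is one of
    ``"F1"``, ``"BC1_toward_<species>"`` or ``"ambiguous"``.
    """

    parent_1: str
    parent_2: str
    dam: str
    sire: str
    generation: str
    stats: GenerationStats
    dam_mito_proportion: float
    tree_concordant: bool | None
    nuclear_census: HitCensus
    mito_census: HitCensus | None = None
    tree_census: SisterCensus | None = None
    warnings_: list[str] = field(default_factory=list)

    @property
    def is_ambiguous(self) -> bool:
        return self.generation == "ambiguous" or self.dam == "ambiguous"

    def to_dict(self) -> dict[str, Any]:
        out = {
            "parent_1": self.parent_1,
            "parent_2": self.parent_2,
            "dam": self.dam,
            "sire": self.sire,
            "generation": self.generation,
            "statistics": {
                "c1_dam_parent": self.stats.c1,
                "c2_other_parent": self.stats.c2,
                "n_effective": self.stats.n_effective,
                "p_hat_dam_parent_share": self.stats.p_hat,
                "p_value_f1": self.stats.p_value_f1,
                "p_value_bc1_parent1": self.stats.p_value_bc1_parent1,
                "p_value_bc1_parent2": self.stats.p_value_bc1_parent2,
                "alpha": self.stats.alpha,
            },
            "dam_mito_proportion": self.dam_mito_proportion,
            "tree_concordant": self.tree_concordant,
            "nuclear_census": self.nuclear_census.to_dict(),
            "warnings": list(self.warnings_),
        }
        if self.mito_census is not None:
            out["mito_census"] = self.mito_census.to_dict()
        if self.tree_census is not None:
            out["tree_census"] = self.tree_census.to_dict()
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        s = self.stats
        lines = [
            "Parentage inference summary",
            "=" * 45,
            f"{'parent 1 (dam lineage)':32s} {self.parent_1}",
            f"{'parent 2':32s} {self.parent_2}",
            f"{'dam (mitochondrial)':32s} {self.dam}",
            f"{'sire':32s} {self.sire}",
            f"{'generation call':32s} {self.generation}",
            "-" * 45,
            f"{'dam-parent hits c1':32s} {s.c1}",
            f"{'other-parent hits c2':32s} {s.c2}",
            f"{'effective n for tests':32s} {s.n_effective}",
            f"{'dam-parent share p-hat':32s} {s.p_hat:.4f}",
            f"{'P(two-sided), H0 p=0.50 (F1)':32s} {s.p_value_f1:.4g}",
            f"{'P(two-sided), H0 p=0.75 (BC1>1)':32s} {s.p_value_bc1_parent1:.4g}",
            f"{'P(two-sided), H0 p=0.25 (BC1>2)':32s} {s.p_value_bc1_parent2:.4g}",
            f"{'alpha':32s} {s.alpha}",
            f"{'dam mito proportion':32s} {self.dam_mito_proportion:.4f}",
        ]
        if self.tree_concordant is not None:
            lines.append(f"{'gene-tree concordance':32s} {self.tree_concordant}")
        if self.warnings_:
            lines.append("-" * 45)
            lines.extend(f"warning: {w}" for w in self.warnings_)
        lines.append(
            "note: read counts overstate independent ancestry observations; "
            "tests use the downsampled effective n above."
        )
        return "\n".join(lines)

    def plot_census(self, ax=None):
        """Bar plot of nuclear census proportions (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.2))
        props = self.nuclear_census.proportions
        names = sorted(props, key=lambda sp: -props[sp])
        ax.bar(names, [props[n] for n in names], color="#4878a8")
        ax.set_ylabel("proportion of unique best hits")
        ax.axhline(F1_SHARE, ls="--", c="grey", lw=0.8)
        ax.tick_params(axis="x", rotation=45)
        return ax


class ParentageModel:
    """Parentage model over nuclear, mitochondrial and gene-tree censuses.

    Parameters
    ----------
    nuclear : HitCensus
        Best-hit census against the nuclear fragment database.
    mito : HitCensus, optional
        Census against the mitochondrial-only database; without it the dam
        is ambiguous.
    trees : SisterCensus, optional
        Gene-tree singleton-sister census, used as a concordance check.
    alpha : float
        Significance level of the exact binomial generation tests.
    dam_threshold : float
        Minimum mito-census proportion for an unambiguous dam call.
    n_eff : int or None
        Effective sample size the parent-assigned counts are downsampled
        to before testing; None disables downsampling.
    """

    def __init__(
        self,
        nuclear: HitCensus,
        mito: HitCensus | None = None,
        trees: SisterCensus | None = None,
        alpha: float = 0.001,
        dam_threshold: float = 0.99,
        n_eff: int | None = 150,
    ) -> None:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.nuclear = nuclear
        self.mito = mito
        self.trees = trees
        self.alpha = alpha
        self.dam_threshold = dam_threshold
        self.n_eff = n_eff

    @classmethod
    def from_counts(
        cls,
        nuclear_counts: dict[str, int],
        mito_counts: dict[str, int] | None = None,
        **kwargs,
    ) -> "ParentageModel":
        """Build the model from plain per-species count mappings."""
        nuc = HitCensus(dict(nuclear_counts), sum(nuclear_counts.values()), 0, 0)
        mito = None
        if mito_counts is not None:
            mito = HitCensus(dict(mito_counts), sum(mito_counts.values()), 0, 0)
        return cls(nuc, mito=mito, **kwargs)

    def fit(self) -> ParentageResults:
        """Run parent identification, dam assignment, and generation tests."""
        notes: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            p1, p2 = identify_parents(self.nuclear)
            if self.mito is not None:
                dam = assign_dam(self.mito, (p1, p2), self.dam_threshold)
            else:
                dam = "ambiguous"
                notes.append("no mitochondrial census supplied")
            notes.extend(str(w.message) for w in caught)

        dam_prop = 0.0
        if self.mito is not None and dam != "ambiguous":
            dam_prop = self.mito.proportions.get(dam, 0.0)
        # order parents dam-first so c1 is the dam-parent count
        if dam == p2:
            p1, p2 = p2, p1
        c1 = self.nuclear.counts.get(p1, 0)
        c2 = self.nuclear.counts.get(p2, 0)
        generation, stats = classify_generation(
            c1, c2, alpha=self.alpha, n_max=self.n_eff
        )
        if generation == "BC1_toward_parent1":
            generation = f"BC1_toward_{p1}"
        elif generation == "BC1_toward_parent2":
            generation = f"BC1_toward_{p2}"
        if dam == "ambiguous":
            sire = "ambiguous"
        else:
            sire = p2 if dam == p1 else p1
        concordant = None
        if self.trees is not None and self.trees.n_singleton > 0:
            props = self.trees.proportions
            top_sister = max(props, key=lambda sp: (props[sp], sp))
            concordant = top_sister in (p1, p2)
        return ParentageResults(
            parent_1=p1,
            parent_2=p2,
            dam=dam,
            sire=sire,
            generation=generation,
            stats=stats,
            dam_mito_proportion=dam_prop,
            tree_concordant=concordant,
            nuclear_census=self.nuclear,
            mito_census=self.mito,
            tree_census=self.trees,
            warnings_=notes,
        )


def write_report(
    results: ParentageResults, path: str | None = None
) -> dict[str, Any]:
    """Write the machine-readable JSON report (and return it as a dict)."""
    payload = results.to_dict()
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    return payload
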