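"""The full two-MSA comparison: per-structure scores, outlier handling,
summaries, and the binomial vote.

Each reference structure casts one vote: the sign of dS = S1 - S2, the
difference of its congruence S-scores under the two alignments.  The
significance of the majority vote is the two-tailed equiprobable binomial
P.  Summaries (mean dS, its SD, the vote, mean distance discrepancies) are
reported twice — with structures flagged by the discrepancy filter in
either MSA removed from both, and with every structure retained.

The per-structure votes are treated as independent; in reality even
low-identity homologous structures are correlated, so the binomial
P-values somewhat overstate significance (see ``ComparisonReport.notes``).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import binom

from . import dca
from .config import RunConfig
from .errors import DataError
from .ica import ica_s_score
from .msa_io import Msa, filter_null_columns
from .outliers import DeltaDTable, delta_d_matrix, iterative_exclusion, select_diverse_structures
from .pair_mapping import build_alignment_map, build_pair_arrays
from .structures import ReferenceStructure

logger = logging.getLogger(__name__)

INDEPENDENCE_NOTE = (
    "Binomial P-values assume independent votes; homologous reference "
    "structures are never fully independent, so reported significances "
    "should be discounted to some extent."
)


def two_tailed_binomial_p(n1: int, n2: int) -> float:
    """Two-tailed equiprobable binomial P of an (n1, n2) vote split.

    ``P = min(1, 2 * sum_{j=k}^{n} C(n, j) / 2^n)`` with n = n1 + n2 and
    k = max(n1, n2).
    """
    if n1 < 0 or n2 < 0:
        raise DataError("vote counts must be non-negative")
    n = n1 + n2
    if n == 0:
        raise DataError("binomial vote undefined for n1 = n2 = 0")
    k = max(n1, n2)
    return min(1.0, 2.0 * float(binom.sf(k - 1, n, 0.5)))


@dataclass
class StructureVerdict:
    """One structure's row of the per-structure table."""

    structure_id: str
    s1: float
    s2: float
    delta_s: float
    delta_d_1: float
    delta_d_2: float
    shared_cols: int  # |R|
    D: int
    L: int
    excluded: bool = False
    reason: str = ""
    subgroup: str = ""

    @property
    def usable(self) -> bool:
        return self.reason != "unusable"


@dataclass
class SummaryBlock:
    """Vote and dS summary over one retained structure set."""

    n_structures: int
    n1: int
    n2: int
    delta_s_mean: float
    delta_s_sd: float
    binomial_p: float
    neg_log10_p: float
    delta_d_mean_1: float
    delta_d_mean_2: float
    degenerate_sd: bool = False
    no_vote: bool = False


@dataclass
class ComparisonReport:
    """Everything a comparison run produced."""

    msa1_label: str
    msa2_label: str
    verdicts: list[StructureVerdict]
    with_exclusion: SummaryBlock | None
    without_exclusion: SummaryBlock
    delta_d_tables: tuple[DeltaDTable, DeltaDTable] | None
    config: dict
    warnings: list[str] = field(default_factory=list)
    notes: str = INDEPENDENCE_NOTE

    def verdicts_frame(self):
        import pandas as pd

        rows = [
            dict(
                pdbid=v.structure_id, S1=v.s1, dD1=v.delta_d_1, S2=v.s2,
                dD2=v.delta_d_2, dS=v.delta_s, cols=v.shared_cols, D=v.D,
                L=v.L, excluded=v.excluded, reason=v.reason,
                subgroup=v.subgroup,
            )
            for v in self.verdicts
        ]
        return pd.DataFrame(rows)

    def summary_frame(self):
        import pandas as pd

        rows = []
        for name, block in (
            ("with_exclusion", self.with_exclusion),
            ("without_exclusion", self.without_exclusion),
        ):
            if block is None:
                continue
            rows.append(dict(block=name, **asdict(block)))
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "msa1": self.msa1_label,
            "msa2": self.msa2_label,
            "config": self.config,
            "verdicts": [asdict(v) for v in self.verdicts],
            "with_exclusion": (
                asdict(self.with_exclusion) if self.with_exclusion else None
            ),
            "without_exclusion": asdict(self.without_exclusion),
            "warnings": self.warnings,
            "notes": self.notes,
        }

    def write(self, prefix: str) -> None:
        self.verdicts_frame().to_csv(f"{prefix}.verdicts.tsv", sep="\t", index=False)
        self.summary_frame().to_csv(f"{prefix}.summary.tsv", sep="\t", index=False)
        with open(f"{prefix}.report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def summarize(verdicts: list[StructureVerdict], use_exclusion: bool) -> SummaryBlock:
    """Aggregate retained verdicts into a vote and dS summary.

    dS = 0 votes for neither side.  A single retained verdict reports
    SD = 0 with the degenerate flag set; an all-zero vote reports P = 1
    with the no-vote flag set.
    """
    retained = [v for v in verdicts if v.usable and not (use_exclusion and v.excluded)]
    if not retained:
        raise DataError("no retained structures to summarise")
    ds = np.array([v.delta_s for v in retained])
    n1 = int((ds > 0).sum())
    n2 = int((ds < 0).sum())
    degenerate = len(ds) < 2
    sd = 0.0 if degenerate else float(ds.std(ddof=1))
    no_vote = (n1 + n2) == 0
    p = 1.0 if no_vote else two_tailed_binomial_p(n1, n2)
    return SummaryBlock(
        n_structures=len(retained),
        n1=n1,
        n2=n2,
        delta_s_mean=float(ds.mean()),
        delta_s_sd=sd,
        binomial_p=p,
        neg_log10_p=-float(np.log10(p)) if p > 0 else float("inf"),
        delta_d_mean_1=float(np.mean([v.delta_d_1 for v in retained])),
        delta_d_mean_2=float(np.mean([v.delta_d_2 for v in retained])),
        degenerate_sd=degenerate,
        no_vote=no_vote,
    )


def _match_sequence_sets(msa1: Msa, msa2: Msa, warnings: list[str]) -> tuple[Msa, Msa]:
    """Restrict both MSAs to their shared ungapped-sequence multiset."""
    seqs1 = [msa1.ungapped(i) for i in range(msa1.n_records)]
    seqs2 = [msa2.ungapped(i) for i in range(msa2.n_records)]
    c1, c2 = Counter(seqs1), Counter(seqs2)
    if c1 == c2:
        return msa1, msa2
    shared = c1 & c2
    if not shared:
        raise DataError("the two MSAs share no sequences")
    only1 = sum((c1 - shared).values())
    only2 = sum((c2 - shared).values())
    msg = (
        f"MSAs do not contain the same sequence set ({only1} unique to "
        f"{msa1.label or 'MSA1'}, {only2} unique to {msa2.label or 'MSA2'}); "
        f"using the {sum(shared.values())} shared sequences"
    )
    logger.warning(msg)
    warnings.append(msg)

    def restrict(msa: Msa, seqs: list[str]) -> Msa:
        budget = Counter(shared)
        keep = []
        for i, s in enumerate(seqs):
            if budget[s] > 0:
                budget[s] -= 1
                keep.append(i)
        return msa.subset(keep)

    return restrict(msa1, seqs1), restrict(msa2, seqs2)


def compare_msas(
    msa1: Msa,
    msa2: Msa,
    structures: list[ReferenceStructure],
    config: RunConfig | None = None,
    scores1: dca.CouplingScores | None = None,
    scores2: dca.CouplingScores | None = None,
    explicit_rows: dict | None = None,
    subgroups: dict[str, str] | None = None,
) -> ComparisonReport:
    """Run the full comparison of two alignments of the same sequences.

    Precomputed DC-score matrices may be passed to skip the internal Potts
    fits.  Structures that cannot be placed in both MSAs, or that yield no
    comparable residue pairs, appear in the verdict table flagged as
    unusable.  The outlier filter runs per MSA and the union of exclusions
    is applied; it needs at least 3 usable structures, otherwise summaries
    are reported without exclusion only.
    """
    config = config or RunConfig()
    warnings: list[str] = []
    label1 = msa1.label or "MSA1"
    label2 = msa2.label or "MSA2"
    msa1, msa2 = _match_sequence_sets(msa1, msa2, warnings)
    msa1 = filter_null_columns(msa1, config.max_null_fraction)
    msa2 = filter_null_columns(msa2, config.max_null_fraction)

    for scores, msa, lab in ((scores1, msa1, label1), (scores2, msa2, label2)):
        if scores is not None and scores.n_cols != msa.n_scored:
            raise DataError(
                f"score matrix for {lab} has {scores.n_cols} columns but the "
                f"alignment has {msa.n_scored} scored columns"
            )
    if scores1 is None:
        logger.info("fitting Potts model for %s", label1)
        scores1 = dca.scores_for_msa(
            msa1, config.reweight_threshold, config.reg_strength
        )
    if scores2 is None:
        logger.info("fitting Potts model for %s", label2)
        scores2 = dca.scores_for_msa(
            msa2, config.reweight_threshold, config.reg_strength
        )

    # place structures in both MSAs
    placed: list[tuple[ReferenceStructure, object]] = []
    unplaced: list[str] = []
    for st in structures:
        amap = build_alignment_map(st, msa1, msa2, explicit_rows)
        if amap is None:
            unplaced.append(st.id)
            warnings.append(f"structure {st.id} not found in both MSAs; skipped")
        else:
            placed.append((st, amap))

    if config.diversity_cutoff is not None and len(placed) > 1:
        kept = select_diverse_structures(
            [st for st, _ in placed],
            [amap.side1 for _, amap in placed],
            config.diversity_cutoff,
        )
        dropped = [placed[i][0].id for i in range(len(placed)) if i not in set(kept)]
        if dropped:
            msg = (
                f"{len(dropped)} structures above {config.diversity_cutoff:.0%} "
                f"identity removed by diversity selection: {dropped}"
            )
            logger.info(msg)
            warnings.append(msg)
        placed = [placed[i] for i in kept]

    min_structures = 1 if config.allow_single_structure else 2
    if len(placed) < min_structures:
        raise DataError(
            f"only {len(placed)} usable reference structures (>= "
            f"{min_structures} required)"
        )
    if len(placed) < 10:
        warnings.append(
            f"only {len(placed)} reference structures; at least 10 are "
            "recommended for a meaningful vote"
        )

    # per-structure S-scores
    verdicts: list[StructureVerdict] = []
    scored: list[int] = []  # indices into `placed` that produced scores
    subgroups = subgroups or {}
    for st, amap in placed:
        try:
            k1, k2 = build_pair_arrays(
                amap, scores1, scores2,
                st.contact_matrix(config.z), st.pairwise_min_distance,
                m=config.min_separation, labels=(label1, label2),
            )
        except DataError as exc:
            warnings.append(str(exc))
            verdicts.append(
                StructureVerdict(
                    st.id, float("nan"), float("nan"), float("nan"),
                    float("nan"), float("nan"), len(amap.r_set), 0, 0,
                    excluded=True, reason="unusable",
                    subgroup=subgroups.get(st.id, ""),
                )
            )
            continue
        r1, r2 = ica_s_score(k1), ica_s_score(k2)
        verdicts.append(
            StructureVerdict(
                st.id, r1.s_score, r2.s_score, r1.s_score - r2.s_score,
                float("nan"), float("nan"), len(amap.r_set), k1.D, k1.L,
                subgroup=subgroups.get(st.id, ""),
            )
        )
        scored.append(len(verdicts) - 1)

    # distance-discrepancy filter, independently per MSA
    delta_d_tables = None
    with_exclusion = None
    usable = [placed[i] for i, v in zip(range(len(placed)), verdicts) if v.usable]
    usable_idx = [i for i, v in enumerate(verdicts) if v.usable]
    if len(usable) >= 2:
        t1 = delta_d_matrix(
            [st for st, _ in usable], [amap.side1 for _, amap in usable], label1
        )
        t2 = delta_d_matrix(
            [st for st, _ in usable], [amap.side2 for _, amap in usable], label2
        )
        for j, vi in enumerate(usable_idx):
            verdicts[vi].delta_d_1 = float(t1.per_structure[j])
            verdicts[vi].delta_d_2 = float(t2.per_structure[j])
        if len(usable) >= 3:
            t1 = iterative_exclusion(t1, config.sd_multiplier)
            t2 = iterative_exclusion(t2, config.sd_multiplier)
            for j, vi in enumerate(usable_idx):
                sid = verdicts[vi].structure_id
                if sid in t1.excluded:
                    verdicts[vi].excluded = True
                    verdicts[vi].reason = "delta_d_msa1"
                elif sid in t2.excluded:
                    verdicts[vi].excluded = True
                    verdicts[vi].reason = "delta_d_msa2"
            with_exclusion = summarize(verdicts, use_exclusion=True)
        else:
            warnings.append(
                "fewer than 3 usable structures; outlier exclusion skipped"
            )
        delta_d_tables = (t1, t2)
    without_exclusion = summarize(verdicts, use_exclusion=False)

    return ComparisonReport(
        msa1_label=label1,
        msa2_label=label2,
        verdicts=verdicts,
        with_exclusion=with_exclusion,
        without_exclusion=without_exclusion,
        delta_d_tables=delta_d_tables,
        config=config.to_dict(),
        warnings=warnings,
    )
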