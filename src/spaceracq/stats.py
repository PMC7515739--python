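"""Strand/positional bias, replicate overlap, double-spacer selection signal
and flank nucleotide preferences for mapped protospacers.

Targeting convention (stated on every report): a protospacer is
*transcript-targeting* when the spacer sequence equals the gene's template
strand there, i.e. the crRNA base-pairs with the mRNA — the protective
configuration for a transcription-dependent Type III system. A gene on "+"
is targeted by hits on "-", and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqmodel import GeneFeature, ReferenceGenome, revcomp

TARGETING_CONVENTION = (
    "targeting = spacer matches the gene template strand (crRNA complementary to mRNA); "
    "gene '+' is targeted by hits on '-' and vice versa"
)


# ---------------------------------------------------------------------------
# Targeting classification
# ---------------------------------------------------------------------------

def classify_targeting(
    start: int, length: int, strand: str, features: Sequence[GeneFeature]
) -> str:
    """'targeting' / 'non_targeting' / 'intergenic' for one protospacer locus.

    A protospacer straddling several genes is assigned to the gene with the
    largest overlap (exact tie -> smaller gene start, deterministic).
    """
    end = start + length
    best = None
    best_key = None
    for f in features:
        ov = min(end, f.end) - max(start, f.start)
        if ov > 0:
            key = (-ov, f.start)
            if best_key is None or key < best_key:
                best, best_key = f, key
    if best is None:
        return "intergenic"
    return "targeting" if best.strand != strand else "non_targeting"


def annotate_clusters(
    clusters: pd.DataFrame,
    references: Mapping[str, ReferenceGenome],
    replicon_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Add targeting, region and replicon columns to a cluster table.

    ``replicon_of`` maps reference ids to {'phage','chromosome',
    'megaplasmid'}; defaults to substring matching on the reference id.
    Region is the named region of the reference containing the protospacer
    midpoint ('NA' outside all named regions). ``temporal_class`` is that
    of the overlapped gene ('NA' for intergenic loci).
    """
    out = clusters.copy()
    targeting, region, replicon, tclass = [], [], [], []
    for row in out.itertuples():
        ref = references[row.reference_id]
        cat = classify_targeting(row.start, row.length, row.strand, ref.features)
        targeting.append(cat)
        mid = row.start + row.length // 2
        reg = "NA"
        for name, (s, e) in ref.regions.items():
            if name in ("hot", "cold") and s <= mid < e:
                reg = name
                break
        region.append(reg)
        if replicon_of and row.reference_id in replicon_of:
            replicon.append(replicon_of[row.reference_id])
        elif "chromosome" in row.reference_id:
            replicon.append("chromosome")
        elif "megaplasmid" in row.reference_id or "plasmid" in row.reference_id:
            replicon.append("megaplasmid")
        else:
            replicon.append("phage")
        tc = "NA"
        if cat != "intergenic":
            end = row.start + row.length
            best, best_key = None, None
            for f in ref.features:
                ov = min(end, f.end) - max(row.start, f.start)
                if ov > 0 and (best_key is None or (-ov, f.start) < best_key):
                    best, best_key = f, (-ov, f.start)
            tc = best.temporal_class
        tclass.append(tc)
    out["targeting"] = targeting
    out["region"] = region
    out["replicon"] = replicon
    out["temporal_class"] = tclass
    return out


# ---------------------------------------------------------------------------
# Strand-bias report
# ---------------------------------------------------------------------------

def _bias_rows(annotated: pd.DataFrame, by: str) -> list[dict]:
    rows = []
    for value, sub in annotated.groupby(by):
        genic = sub[sub["targeting"] != "intergenic"]
        for weighted in (False, True):
            w = genic["read_count"] if weighted else pd.Series(1, index=genic.index)
            n_t = int(w[genic["targeting"] == "targeting"].sum())
            n_n = int(w[genic["targeting"] == "non_targeting"].sum())
            frac = n_t / (n_t + n_n) if (n_t + n_n) else float("nan")
            rows.append(
                {
                    "category": by,
                    "value": value,
                    "weighting": "all_spacers" if weighted else "unique_spacers",
                    "n_targeting": n_t,
                    "n_nontargeting": n_n,
                    "fraction_targeting": frac,
                }
            )
    return rows


def strand_bias_report(annotated: pd.DataFrame) -> dict:
    """Targeting fractions per replicon, temporal class and region.

    Every fraction is computed twice: read-count weighted ("all spacers")
    and unweighted over clusters ("unique spacers"). Also reports the
    phage-derived fraction of all spacers (weighted and unweighted).
    Categories with no genic spacers yield NaN fractions.
    """
    rows = []
    rows += _bias_rows(annotated, "replicon")
    rows += _bias_rows(annotated[annotated["temporal_class"] != "NA"], "temporal_class")
    rows += _bias_rows(annotated[annotated["region"] != "NA"], "region")
    table = pd.DataFrame(rows)

    total_w = annotated["read_count"].sum()
    phage_w = annotated.loc[annotated["replicon"] == "phage", "read_count"].sum()
    return {
        "convention": TARGETING_CONVENTION,
        "table": table,
        "phage_fraction_weighted": float(phage_w / total_w) if total_w else float("nan"),
        "phage_fraction_unweighted": float(
            (annotated["replicon"] == "phage").mean()
        ) if len(annotated) else float("nan"),
    }


# ---------------------------------------------------------------------------
# Replicate overlap
# ---------------------------------------------------------------------------

def jaccard_overlap(set_a: set, set_b: set) -> float:
    """|A∩B| / |A∪B| over distinct spacer sequences; NaN when both empty."""
    union = set_a | set_b
    if not union:
        return float("nan")
    return len(set_a & set_b) / len(union)


# ---------------------------------------------------------------------------
# Double-spacer selection analysis
# ---------------------------------------------------------------------------

@dataclass
class DoubleSpacerStats:
    n_reads_total: int
    n_reads_two_spacers: int
    fraction_double: float
    observed: dict  # region -> count among double-read spacers
    expected: dict  # region -> expected count under the single-spacer law
    chi_square: float
    df: int
    p_value: float
    # among double-read spacers in the cold region:
    cold_fraction_leader_proximal: float  # ordinal == 1 (newest)
    cold_fraction_leader_distal: float  # ordinal > 1
    notes: str = (
        "ordinal 1 = leader-proximal = acquired last; both ordinal "
        "compositions are reported"
    )


def double_spacer_analysis(
    spacer_table: pd.DataFrame,
    regions: Sequence[str] = ("hot", "cold"),
    single_distribution: Mapping[str, float] | None = None,
) -> DoubleSpacerStats:
    """Region composition of spacers from two-spacer reads vs the single law.

    ``spacer_table`` needs columns read_id, ordinal, region. The expected
    region proportions default to the empirical distribution of spacers
    from single-spacer reads; a chi-square goodness-of-fit (no continuity
    correction, df = #regions - 1) compares the double-read composition
    against it.
    """
    tab = spacer_table[spacer_table["region"].isin(regions)]
    per_read = spacer_table.groupby("read_id")["ordinal"].size()
    n_total = int(per_read.size)
    doubles = set(per_read[per_read == 2].index)
    n_double = len(doubles)

    singles = set(per_read[per_read == 1].index)
    single_tab = tab[tab["read_id"].isin(singles)]
    double_tab = tab[tab["read_id"].isin(doubles)]

    if single_distribution is None:
        counts = single_tab["region"].value_counts()
        tot = counts.sum()
        if tot == 0:
            raise ValueError("no single-spacer reads to build the expected distribution")
        single_distribution = {r: counts.get(r, 0) / tot for r in regions}

    observed = np.array([int((double_tab["region"] == r).sum()) for r in regions])
    n_obs = observed.sum()
    expected = np.array([single_distribution[r] * n_obs for r in regions])
    if ((expected == 0) & (observed > 0)).any():
        raise ValueError(
            "expected count 0 in a nonempty observed cell; merge regions or "
            "provide a non-degenerate single-spacer distribution"
        )
    if n_obs == 0:
        chi2, p = 0.0, 1.0
    else:
        keep = expected > 0
        chi2, p = sps.chisquare(observed[keep], expected[keep])
    df = len(regions) - 1

    cold = double_tab[double_tab["region"] == "cold"]
    if len(cold):
        f_prox = float((cold["ordinal"] == 1).mean())
        f_dist = float((cold["ordinal"] > 1).mean())
    else:
        f_prox = f_dist = float("nan")

    return DoubleSpacerStats(
        n_reads_total=n_total,
        n_reads_two_spacers=n_double,
        fraction_double=n_double / n_total if n_total else float("nan"),
        observed={r: int(o) for r, o in zip(regions, observed)},
        expected={r: float(e) for r, e in zip(regions, expected)},
        chi_square=float(chi2),
        df=df,
        p_value=float(p),
        cold_fraction_leader_proximal=f_prox,
        cold_fraction_leader_distal=f_dist,
    )


# ---------------------------------------------------------------------------
# Flank nucleotide preferences
# ---------------------------------------------------------------------------

@dataclass
class FlankMatrix:
    """Position frequency matrix around protospacers, 5'->3' on the
    protospacer strand: ``flank`` upstream columns, ``window`` protospacer
    columns, ``flank`` downstream columns."""

    frequencies: pd.DataFrame  # rows A,C,G,T; columns positions
    counts: pd.DataFrame
    flank: int
    window: int
    n_used: int
    n_skipped: int  # protospacers too close to a reference end


def flank_matrix(
    clusters: pd.DataFrame,
    references: Mapping[str, ReferenceGenome],
    flank: int = 10,
    window: int = 35,
    weighted: bool = False,
) -> FlankMatrix:
    """Base frequencies in and around protospacers (PAM check for a system
    that should not have one).

    For '-' strand hits the extracted region is reverse-complemented so all
    columns read 5'->3' along the protospacer strand. Protospacers within
    ``flank`` bp of a reference end are skipped and counted.
    """
    if not len(clusters):
        raise ValueError("no clusters to build a flank matrix from")
    ncol = 2 * flank + window
    counts = np.zeros((4, ncol), dtype=float)
    base_row = {b: i for i, b in enumerate("ACGT")}
    used = skipped = 0
    for row in clusters.itertuples():
        ref = references[row.reference_id]
        s, e = row.start, row.start + row.length
        if s - flank < 0 or e + flank > len(ref.sequence):
            skipped += 1
            continue
        region = ref.sequence[s - flank : e + flank]
        if row.strand == "-":
            region = revcomp(region)
        region = region[: flank + window] + region[len(region) - flank :]
        w = row.read_count if weighted else 1
        for j, b in enumerate(region[:ncol]):
            if b in base_row:
                counts[base_row[b], j] += w
        used += 1
    col_tot = counts.sum(axis=0)
    freqs = np.divide(counts, col_tot, out=np.zeros_like(counts), where=col_tot > 0)
    cols = (
        [f"up{-(i - flank)}" for i in range(flank)]
        + [f"p{i + 1}" for i in range(window)]
        + [f"down{i + 1}" for i in range(flank)]
    )
    idx = list("ACGT")
    return FlankMatrix(
        frequencies=pd.DataFrame(freqs, index=idx, columns=cols),
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        flank=flank,
        window=window,
        n_used=used,
        n_skipped=skipped,
    )
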