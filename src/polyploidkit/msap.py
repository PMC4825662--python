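"""MSAP cytosine-methylation scoring and analysis.

Methylation-sensitive amplified polymorphism (MSAP) profiles each
5'-CCGG site with two parallel digests using the isoschizomers HpaII
and MspI, which share the recognition site but differ in methylation
sensitivity.  The band pair (HpaII, MspI) at one gel position maps to a
methylation state:

=========  ======  =========================================
band pair  state   interpretation
=========  ======  =========================================
1-1        U       unmethylated CCGG
1-0        H       hemi-methylated site
0-1        F       fully methylated internal cytosine (CmCGG)
0-0        X       uninformative (mutation or mCmCGG), excluded
=========  ======  =========================================

Comparing each hybrid's state with its two parents' states classifies
the site into monomorphic, parental-pattern inheritance (either
parent), de novo methylation, demethylation, or ambiguous, using the
methylation order U < H < F.  The module also computes group
methylation levels, the MR statistic (percent de novo methylation over
percent demethylation), one-way ANOVA of levels, and principal
coordinates analysis of the binary band profiles.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "STATES",
    "SITE_CLASSES",
    "score_state",
    "state_to_bands",
    "classify_site",
    "score_band_matrix",
    "classify_hybrid_sites",
    "methylation_levels",
    "methylation_ratio",
    "class_summary",
    "compare_methylation_levels",
    "pcoa_profiles",
]

STATES = ("U", "H", "F")
_ORDER = {"U": 0, "H": 1, "F": 2}

SITE_CLASSES = (
    "monomorphic",
    "parental_P1_like",
    "parental_P2_like",
    "demethylation",
    "de_novo_methylation",
    "ambiguous",
    "excluded",
)

_BAND_TO_STATE = {(1, 1): "U", (1, 0): "H", (0, 1): "F", (0, 0): "X"}
_STATE_TO_BAND = {v: k for k, v in _BAND_TO_STATE.items()}


def score_state(band_hpa: int, band_msp: int) -> str:
    """Methylation state of one site from its HpaII/MspI band pair."""
    if band_hpa not in (0, 1) or band_msp not in (0, 1):
        raise ValueError(f"band values must be 0 or 1, got ({band_hpa!r}, {band_msp!r})")
    return _BAND_TO_STATE[(band_hpa, band_msp)]


def state_to_bands(state: str) -> tuple[int, int]:
    """Inverse of :func:`score_state`: (HpaII, MspI) bands for a state."""
    try:
        return _STATE_TO_BAND[state]
    except KeyError:
        raise ValueError(f"unknown methylation state {state!r}") from None


def classify_site(state_p1: str, state_p2: str, state_hybrid: str) -> str:
    """Inheritance class of one site from the (parent1, parent2, hybrid) states.

    Decision table over the methylation order U < H < F: any
    uninformative state excludes the site; three equal states are
    monomorphic; if the parents differ and the hybrid matches exactly
    one, the site shows parental-pattern inheritance; a hybrid strictly
    more (less) methylated than both parents shows de novo methylation
    (demethylation); anything else — a hybrid strictly between
    discordant parents — is ambiguous.
    """
    for s in (state_p1, state_p2, state_hybrid):
        if s not in ("U", "H", "F", "X"):
            raise ValueError(f"unknown methylation state {s!r}")
    if "X" in (state_p1, state_p2, state_hybrid):
        return "excluded"
    if state_p1 == state_p2 == state_hybrid:
        return "monomorphic"
    if state_p1 != state_p2:
        if state_hybrid == state_p1:
            return "parental_P1_like"
        if state_hybrid == state_p2:
            return "parental_P2_like"
    o1, o2, oh = _ORDER[state_p1], _ORDER[state_p2], _ORDER[state_hybrid]
    if oh > o1 and oh > o2:
        return "de_novo_methylation"
    if oh < o1 and oh < o2:
        return "demethylation"
    return "ambiguous"


def score_band_matrix(bands: pd.DataFrame) -> pd.DataFrame:
    """Convert a two-lane band matrix into per-individual site states.

    ``bands`` is indexed by (individual, lane) with lanes ``HpaII`` and
    ``MspI`` and one 0/1 column per site; the result is individuals ×
    sites with values in {U, H, F, X}.
    """
    lanes = bands.index.get_level_values(1)
    expected = {"HpaII", "MspI"}
    if set(lanes) != expected:
        raise ValueError(f"band matrix lanes must be {expected}, got {set(lanes)}")
    hpa = bands.xs("HpaII", level=1)
    msp = bands.xs("MspI", level=1).reindex(hpa.index)
    bad = ~hpa.isin((0, 1)) | ~msp.isin((0, 1))
    if bad.to_numpy().any():
        ind, site = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-binary band value for individual {hpa.index[ind]!r}, "
            f"site {hpa.columns[site]!r}"
        )
    states = np.empty(hpa.shape, dtype=object)
    for (h, m), s in _BAND_TO_STATE.items():
        states[(hpa.to_numpy() == h) & (msp.to_numpy() == m)] = s
    return pd.DataFrame(states, index=hpa.index, columns=hpa.columns)


def classify_hybrid_sites(
    states: pd.DataFrame,
    parent1: str,
    parent2: str,
    hybrids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Classify every (hybrid, site) against the two parents.

    Returns a sites × hybrids frame of class labels.
    """
    if hybrids is None:
        hybrids = [i for i in states.index if i not in (parent1, parent2)]
    out = {}
    p1 = states.loc[parent1]
    p2 = states.loc[parent2]
    for hyb in hybrids:
        hs = states.loc[hyb]
        out[hyb] = [classify_site(a, b, c) for a, b, c in zip(p1, p2, hs)]
    return pd.DataFrame(out, index=states.columns)


def methylation_levels(
    states: pd.DataFrame | Iterable[str], *, per_individual: bool = False
) -> pd.Series | pd.DataFrame:
    """Frequencies of U, H and F among scored (non-X) sites.

    With a states frame (individuals × sites), ``per_individual=True``
    returns one frequency row per individual; otherwise sites are
    pooled across the group.  The frequencies sum to 1 over {U, H, F}.
    """
    if isinstance(states, pd.DataFrame):
        if per_individual:
            rows = {
                ind: methylation_levels(states.loc[ind]) for ind in states.index
            }
            return pd.DataFrame(rows).T[list(STATES)]
        flat: Iterable[str] = states.to_numpy().ravel()
    else:
        flat = states
    counts = pd.Series(list(flat)).value_counts()
    scored = sum(int(counts.get(s, 0)) for s in STATES)
    if scored == 0:
        raise ValueError("no scored (non-X) sites")
    return pd.Series({s: counts.get(s, 0) / scored for s in STATES})


def methylation_ratio(
    n_de_novo: int, n_demethylation: int, n_total: int | None = None
) -> float | None:
    """MR statistic: percent de novo methylation over percent demethylation.

    Both percentages share the same denominator, so MR reduces to the
    count ratio; it is reported to one decimal and is undefined
    (``None``) when no demethylation site was observed.
    """
    if n_total is not None and n_total <= 0:
        raise ValueError("total site count must be positive")
    if n_de_novo < 0 or n_demethylation < 0:
        raise ValueError("class counts must be nonnegative")
    if n_demethylation == 0:
        return None
    return round(n_de_novo / n_demethylation, 1)


def class_summary(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-hybrid site-class counts, percentages and MR.

    ``classes`` is the sites × hybrids frame from
    :func:`classify_hybrid_sites`.  ``total`` counts the scored
    (non-excluded) sites of each hybrid; percentages use that
    denominator.
    """
    rows = []
    for hyb in classes.columns:
        counts = classes[hyb].value_counts()
        total = int(sum(counts.get(c, 0) for c in SITE_CLASSES if c != "excluded"))
        row: dict[str, object] = {"genotype": hyb, "total": total}
        for c in SITE_CLASSES:
            n = int(counts.get(c, 0))
            row[c] = n
            if c != "excluded" and total:
                row[f"{c}_pct"] = round(100.0 * n / total, 2)
        mr = methylation_ratio(
            int(counts.get("de_novo_methylation", 0)),
            int(counts.get("demethylation", 0)),
            total or None,
        )
        row["MR"] = mr if mr is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_methylation_levels(
    groups: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """One-way ANOVA of per-individual methylation levels between groups.

    ``groups`` maps a group label to an individuals × (U, H, F)
    frequency frame (see :func:`methylation_levels` with
    ``per_individual=True``).  Returns one (F, p) row per state.  A
    fully degenerate input (identical values everywhere) yields F = 0,
    p = 1.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    for label, frame in groups.items():
        if len(frame) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 individuals")
    rows = {}
    for state in STATES:
        samples = [np.asarray(frame[state], dtype=float) for frame in groups.values()]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            rows[state] = {"F": 0.0, "p": 1.0}
            continue
        f, p = stats.f_oneway(*samples)
        rows[state] = {"F": float(f), "p": float(p)}
    return pd.DataFrame(rows).T


def pcoa_profiles(
    bands: pd.DataFrame, distance: str = "jaccard"
) -> tuple[pd.DataFrame, pd.Series]:
    """Principal coordinates analysis of MSAP band profiles.

    The two lanes of each individual are concatenated into one binary
    vector, pairwise distances (Jaccard by default) are computed and
    classically scaled.  Returns the coordinates (individuals × axes)
    and the explained-variance fraction per axis.  Negative eigenvalues
    of non-Euclidean distance matrices are truncated to zero by the
    ordination backend, with a warning.
    """
    individuals = bands.index.get_level_values(0).unique()
    if len(individuals) < 3:
        raise ValueError("PCoA needs at least 3 individuals")
    vectors = np.vstack(
        [
            np.concatenate(
                [
                    bands.loc[(ind, "HpaII")].to_numpy(dtype=float),
                    bands.loc[(ind, "MspI")].to_numpy(dtype=float),
                ]
            )
            for ind in individuals
        ]
    )
    dmat = squareform(pdist(vectors, metric=distance))
    # All-identical pairs give 0/0 under Jaccard in scipy; define as 0.
    dmat = np.nan_to_num(dmat, nan=0.0)
    result = _skbio_pcoa(DistanceMatrix(dmat, ids=list(individuals)))
    coords = result.samples
    coords.index = pd.Index(individuals, name="individual")
    explained = result.proportion_explained
    return coords, explained
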