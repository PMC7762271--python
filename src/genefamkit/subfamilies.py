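"""Subfamily consensus models for the ERF clade.

The AP2/ERF superfamily splits by domain architecture (ERF: one AP2
domain; AP2: two; RAV: AP2 + B3), and the single-domain ERF clade further
splits into ERF, DREB, DREB-related factors (DRF) and the divergent
SOLOIST group.  Published catalogues delegate that finer split to curated
reference sets; here the split is operationalised as nearest labelled
reference domain.  This module derives the labelled consensus sequences
deterministically from the AP2 profile: DREB/DRF consensuses substitute
disjoint fixed sets of 10 diagnostic columns, and the SOLOIST consensus
substitutes a fixed 35% of columns (its divergence knob).  The shipped
reference fixture is generated from these functions, so generator and
classifier agree by construction.
"""

from __future__ import annotations

import numpy as np

from .domain_scan import AA_ALPHABET, AA_INDEX, DomainProfile

#: seed fixing the diagnostic column sets and replacement residues
SUBFAMILY_SEED = 20847

N_DIAGNOSTIC = 10
SOLOIST_DIVERGENCE = 0.35

ERF_CLADE_LABELS = ("ERF", "DREB", "DRF", "SOLOIST")


def _substitute(consensus: str, positions, offset: int) -> str:
    out = list(consensus)
    for p in positions:
        out[p] = AA_ALPHABET[(AA_INDEX[out[p]] + offset) % 20]
    return "".join(out)


def diagnostic_columns(profile: DomainProfile) -> dict[str, np.ndarray]:
    """Fixed, disjoint column sets that distinguish the ERF-clade labels."""
    rng = np.random.default_rng(SUBFAMILY_SEED)
    perm = rng.permutation(profile.length)
    n_sol = round(SOLOIST_DIVERGENCE * profile.length)
    return {
        "DREB": perm[:N_DIAGNOSTIC],
        "DRF": perm[N_DIAGNOSTIC : 2 * N_DIAGNOSTIC],
        "SOLOIST": perm[2 * N_DIAGNOSTIC : 2 * N_DIAGNOSTIC + n_sol],
        "_tweak": perm[2 * N_DIAGNOSTIC + n_sol : 2 * N_DIAGNOSTIC + n_sol + 3],
    }


def subfamily_consensuses(profile: DomainProfile) -> dict[str, str]:
    """Consensus domain sequence for each ERF-clade subfamily."""
    cols = diagnostic_columns(profile)
    cons = profile.consensus
    return {
        "ERF": cons,
        "DREB": _substitute(cons, cols["DREB"], 7),
        "DRF": _substitute(cons, cols["DRF"], 7),
        "SOLOIST": _substitute(cons, cols["SOLOIST"], 7),
    }


def reference_records(profile: DomainProfile) -> list[tuple[str, str, str]]:
    """Labelled reference domains as (record_name, label, sequence).

    Two references per label: the subfamily consensus plus a lightly
    perturbed variant (3 substitutions at fixed non-diagnostic columns).
    """
    cols = diagnostic_columns(profile)
    records = []
    for label, cons in subfamily_consensuses(profile).items():
        records.append((f"{label}_ref_1", label, cons))
        records.append((f"{label}_ref_2", label, _substitute(cons, cols["_tweak"], 11)))
    return records
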