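"""Reference compound panel and synthetic score generator.

The panel is the 23 known primary aromatic amines used to probe
substituent effects: aniline as the zero reference, methyl-, methoxy-,
sulfonate- and sulfonamide-substituted anilines, and compounds from
published regulatory expert reviews.  SMILES were resolved once from the
printed CAS numbers/names at authoring time and are embedded as reviewed
constants; commercial-tool calls are carried as annotation strings only.

The synthetic generator emulates the observed separation of ddE scores
between mutagens (low ddE) and nonmutagens (high ddE) for exercising the
metric and cutoff-sweep layers without any quantum chemistry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np


@dataclass(frozen=True)
class ReferenceCompound:
    no: int
    cas: str
    name: str
    smiles: str
    ames: str          # "mutagen" | "nonmutagen"
    ddE_ref: float   # printed ddE, kcal/mol
    annotations: dict  # commercial-tool calls, uninterpreted


def reference_set() -> list[ReferenceCompound]:
    """The 23-compound reference panel."""
    path = resources.files("nitrenium.data").joinpath("reference_panel.csv")
    out = []
    with path.open() as fh:
        for row in csv.DictReader(fh):
            out.append(ReferenceCompound(
                no=int(row["no"]),
                cas=row["cas"],
                name=row["name"],
                smiles=row["smiles"],
                ames=row["ames"],
                ddE_ref=float(row["ddE_ref"]),
                annotations={k: row[k] for k in
                             ("gt1_bmut", "leadscope", "derek", "gt_expert")},
            ))
    if len(out) != 23:
        raise RuntimeError("reference panel must contain 23 compounds")
    return out


def synthetic_scores(n_mut: int, n_non: int, mu_mut: float = -8.0,
                     mu_non: float = 8.0, sd: float = 5.0,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[np.ndarray, list[str]]:
    """Gaussian ddE scores per class, reproducible under seed.

    Returns (scores, labels) with mutagens first.  Class means/spread
    default to a separation comparable to the observed mutagen vs
    nonmutagen score distributions.
    """
    if n_mut <= 0 or n_non <= 0:
        raise ValueError("class counts must be positive")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    scores = np.concatenate([
        rng.normal(mu_mut, sd, n_mut),
        rng.normal(mu_non, sd, n_non),
    ])
    labels = ["mutagen"] * n_mut + ["nonmutagen"] * n_non
    return scores, labels
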