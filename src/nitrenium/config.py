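"""Run configuration for the ddE scoring pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ScoreConfig:
    """Tunable parameters of the nitrenium-stability scorer.

    Defaults reproduce the published protocol: a 7 kcal/mol conformer
    energy window, classification cutoff at 0 kcal/mol (sign rule), and
    scoring of the neutral species only.
    """

    # conformational sampling
    window: float = 7.0            # kcal/mol above the ensemble minimum
    rmsd_threshold: float = 0.5    # heavy-atom RMSD dedup threshold, Angstrom
    min_trials: int = 20           # embedding attempts, scaled by flexibility
    max_trials: int = 300
    trials_per_rotatable: int = 30
    seed: int = 20220321

    # cation protocol: optimise the nitrenium from every windowed neutral
    # conformer and keep the minimum (True), or only from the single most
    # stable neutral conformer (False)
    cation_from_all_conformers: bool = True

    # classification
    cutoff: float = 0.0            # kcal/mol; ddE < cutoff => mutagenic
    equivocal_band: float | None = None  # e.g. 5.0 flags |ddE| < band

    # eligibility handling
    force: bool = False            # score ineligible compounds anyway

    # engine
    engine: str = "am1"            # "am1" | "mopac" | "mock"
    engine_path: str | None = None  # external executable for "mopac"
    timeout: float = 300.0         # seconds per species (external engines)
    gtol: float = 0.012            # eV/A, built-in optimiser convergence

    extra: dict = field(default_factory=dict)


def make_engine(config: ScoreConfig):
    """Instantiate the engine selected by ``config``."""
    if config.engine == "am1":
        from .qm.am1.engine import AM1Engine
        return AM1Engine(gtol=config.gtol)
    if config.engine == "mopac":
        from .qm.mopac import MopacEngine
        if not config.engine_path:
            raise ValueError("engine 'mopac' requires engine_path")
        return MopacEngine(config.engine_path, timeout=config.timeout)
    if config.engine == "mock":
        from .qm.mock import MockEngine
        return MockEngine(**config.extra.get("mock", {}))
    raise ValueError(f"unknown engine '{config.engine}'")
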