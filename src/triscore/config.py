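"""Flat key=value run configuration.

Every tunable of the pipeline lives here with its default; unknown keys in a
config file are rejected, and each run writes the resolved configuration next
to its outputs so results are reproducible from the run directory alone.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    # database / digestion
    decoy_prefix: str = "Rev_"
    max_missed_cleavages: int = 3
    peptide_length_min: int = 6
    peptide_length_max: int = 60
    # search tolerances (wide-window default suits the synthetic ion-trap-style spectra)
    precursor_tolerance: float = 0.5
    precursor_unit: str = "Da"  # "Da" or "ppm"
    fragment_tolerance: float = 0.5
    assumed_charges: str = "2,3"  # used when an MGF block lacks CHARGE
    # two-tier ensemble search
    tier2_depth: int = 50
    output_depth: int = 5
    batch_size: int = 20000
    n_workers: int = 1
    # filtering
    target_fdr: float = 0.01
    fdr_level: str = "psm"  # psm | peptide | protein
    model_kind: str = "logistic_regression"
    alpha: float = 0.5
    split_seed: int = 20170922
    spectrum_count_depth: str = "all_reported"  # or "rank1"
    # assembly
    min_unique_peptides: int = 1

    @property
    def length_range(self) -> tuple[int, int]:
        return (self.peptide_length_min, self.peptide_length_max)

    @property
    def assumed_charge_list(self) -> tuple[int, ...]:
        return tuple(int(z) for z in self.assumed_charges.split(","))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            kwargs[key] = value.strip()
        defaults = cls()
        coerced = {}
        for key, raw in kwargs.items():
            default = getattr(defaults, key)
            if isinstance(default, bool):
                coerced[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                coerced[key] = int(raw)
            elif isinstance(default, float):
                coerced[key] = float(raw)
            else:
                coerced[key] = raw
        return cls(**coerced)
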