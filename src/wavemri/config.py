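"""Pipeline configuration and its plain key=value file format."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

__all__ = ["PipelineConfig", "read_config", "write_config"]


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline with their defaults.

    ``resize_h``/``resize_w`` of 0 disable resizing (images keep their
    native size).  ``lda_ridge`` is the relative ridge epsilon: the ridge
    added to the within-class scatter is ``lda_ridge * trace(VAR_W) / r``.
    ``lda_dims`` is capped at c - 1 at fit time.
    """

    resize_h: int = 240
    resize_w: int = 320
    equalize: str = "on"            # on | off
    wavelet: str = "sym4"
    levels: int = 4
    boundary_mode: str = "periodization"
    feature_mode: str = "rough+freq"  # rough | freq | rough+freq
    mi_bins: int = 64
    lda_dims: int = 24
    lda_ridge: float = 1e-4
    penalty: str = "l2"             # l2 | l1 | elasticnet
    C: float = 1.0
    mix: float = 0.5
    scheme: str = "one-vs-rest"     # one-vs-rest | multinomial
    tol: float = 1e-6
    max_iter: int = 1000
    n_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def read_config(path) -> PipelineConfig:
    """Read a key=value config file; unknown keys are rejected."""
    kwargs = {}
    ftypes = {f.name: f.type for f in fields(PipelineConfig)}
    defaults = PipelineConfig()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in ftypes:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return PipelineConfig(**kwargs)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        for key, value in config.to_dict().items():
            fh.write(f"{key} = {value}\n")
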