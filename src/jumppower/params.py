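"""The optimisation parameter space: data-processing parameters shared by
all model families plus the family-specific hyperparameters.

Parameters are one of three types.  Integers (I) are stored as whole
numbers on an index scale (e.g. the window times t_pre/t_post count 0.1 s
steps).  Reals (R) are continuous; most are stored as log10 exponents and
de-transformed when the pipeline consumes them (the basis density rho is
the exception: it is linear-scale, functions per second).  Categoricals (C)
are stored as 1-based indices into their category list.

Two ranges are attached to each parameter: the *wide* range used by the
random search (extending beyond the optimisation bounds to populate a
border region so the surrogate is well-defined at the periphery) and the
*bounds* used by particle swarm optimisation, padded by 0.50 below and
0.49 above for integer/categorical parameters so rounding is unbiased at
the limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PHI_CODES = ("4-2", "5-2", "5-3", "6-2", "6-3", "6-4")

LR_REGULARISATIONS = ("Ridge", "Lasso")
LR_SOLVERS = ("SVM", "Least Squares")
SVM_KERNELS = ("Gaussian", "Linear", "Polynomial")
GPR_BASES = ("None", "Constant", "Linear", "Pure Quadratic")
GPR_KERNELS = (
    "Exponential",
    "Squared Exponential",
    "Matern 3/2",
    "Matern 5/2",
    "Rational Quadratic",
)

FAMILIES = ("LR", "SVM", "GPR")


@dataclass(frozen=True)
class ParamDef:
    """One optimisation parameter: type, ranges and decoding rule."""

    name: str
    ptype: str  # 'I', 'R' or 'C'
    wide: tuple[float, float]
    bounds: tuple[float, float]
    categories: tuple[str, ...] | None = None
    log10: bool = False       # decode 10**x (R only)
    scale: float = 1.0        # decode scale * x (I only; t_pre/t_post -> s)

    def __post_init__(self):
        if self.ptype not in "IRC":
            raise ValueError(f"unknown parameter type {self.ptype!r}")
        if self.ptype == "C" and not self.categories:
            raise ValueError(f"{self.name}: categorical without categories")

    def round(self, x: float) -> float:
        if self.ptype in "IC":
            return float(np.round(x))
        return float(x)

    def decode(self, x: float):
        if self.ptype == "C":
            idx = int(np.round(x))
            if not 1 <= idx <= len(self.categories):
                raise ValueError(f"{self.name}: category index {idx} out of range")
            return self.categories[idx - 1]
        if self.ptype == "I":
            return int(np.round(x)) * self.scale if self.scale != 1.0 else int(np.round(x))
        return 10.0**x if self.log10 else float(x)


def _data_params() -> list[ParamDef]:
    return [
        ParamDef("t_pre", "I", (-5, 35), (0.51, 30.49), scale=0.1),
        ParamDef("t_post", "I", (-5, 35), (0.51, 30.49), scale=0.1),
        ParamDef("rho", "R", (2.0, 22.0), (4.0, 20.0)),
        ParamDef("phi", "C", (0.51, 6.49), (0.51, 6.49), categories=PHI_CODES),
        ParamDef("lam", "R", (-12.0, 12.0), (-10.0, 10.0), log10=True),
        ParamDef("n_fpc", "I", (1, 35), (3.51, 30.49)),
        ParamDef("standardize", "C", (0.51, 2.49), (0.51, 2.49), categories=("No", "Yes")),
    ]


_FAMILY_PARAMS = {
    "LR": [
        ParamDef("lr_reg", "C", (0.51, 2.49), (0.51, 2.49), categories=LR_REGULARISATIONS),
        ParamDef("lr_solver", "C", (0.51, 2.49), (0.51, 2.49), categories=LR_SOLVERS),
        ParamDef("lam_lr", "R", (-12.0, 12.0), (-10.0, 10.0), log10=True),
    ],
    "SVM": [
        ParamDef("svm_kernel", "C", (0.51, 3.49), (0.51, 3.49), categories=SVM_KERNELS),
        ParamDef("box_constraint", "R", (-7.0, 9.0), (-6.0, 8.0), log10=True),
        ParamDef("kernel_scale", "R", (-7.0, 9.0), (-6.0, 8.0), log10=True),
        ParamDef("epsilon", "R", (-5.0, 3.0), (-4.0, 2.0), log10=True),
    ],
    "GPR": [
        ParamDef("gpr_basis", "C", (0.51, 4.49), (0.51, 4.49), categories=GPR_BASES),
        ParamDef("gpr_kernel", "C", (0.51, 5.49), (0.51, 5.49), categories=GPR_KERNELS),
        ParamDef("sigma", "R", (-5.0, 3.0), (-4.0, 2.0), log10=True),
    ],
}


@dataclass
class ParamSpace:
    """The free parameters being optimised plus any frozen assignments.

    Frozen parameters (fixed by a refinement round) keep their stored
    internal value and are re-inserted at decode time.
    """

    params: list[ParamDef]
    frozen: dict[str, float] = field(default_factory=dict)

    @classmethod
    def for_family(cls, family: str) -> "ParamSpace":
        if family not in FAMILIES:
            raise ValueError(f"unknown model family {family!r}")
        return cls(params=_data_params() + list(_FAMILY_PARAMS[family]))

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def ndim(self) -> int:
        return len(self.params)

    def __getitem__(self, name: str) -> ParamDef:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([p.bounds[0] for p in self.params])
        hi = np.array([p.bounds[1] for p in self.params])
        return lo, hi

    def sample_wide(self, rng: np.random.Generator) -> np.ndarray:
        """One uniform candidate over the wide search ranges (internal rep;
        integers and categoricals already whole)."""
        x = np.empty(self.ndim)
        for k, p in enumerate(self.params):
            lo, hi = p.wide
            if p.ptype == "I":
                x[k] = rng.integers(int(lo), int(hi) + 1)
            elif p.ptype == "C":
                x[k] = rng.integers(1, len(p.categories) + 1)
            else:
                x[k] = rng.uniform(lo, hi)
        return x

    def round_vector(self, x: np.ndarray) -> np.ndarray:
        x = np.array(x, dtype=float)
        if x.ndim == 1:
            for k, p in enumerate(self.params):
                x[k] = p.round(x[k])
            return x
        for k, p in enumerate(self.params):
            x[:, k] = np.round(x[:, k]) if p.ptype in "IC" else x[:, k]
        return x

    def decode(self, x: np.ndarray) -> dict:
        """Internal vector -> pipeline values (seconds, categories, linear
        scale), including frozen parameters."""
        out = {p.name: p.decode(v) for p, v in zip(self.params, x)}
        for name, v in self.frozen.items():
            out[name] = _ALL_DEFS[name].decode(v)
        return out

    def freeze(self, assignments: dict[str, float]) -> "ParamSpace":
        """Return a narrowed space with the named parameters fixed at the
        given internal values (removed from optimisation)."""
        frozen = dict(self.frozen)
        keep = []
        for p in self.params:
            if p.name in assignments:
                frozen[p.name] = p.round(assignments[p.name])
            else:
                keep.append(p)
        if not keep:
            raise ValueError("all parameters frozen; nothing left to optimise")
        return replace(self, params=keep, frozen=frozen)


_ALL_DEFS = {p.name: p for p in _data_params()}
for _fam in _FAMILY_PARAMS.values():
    _ALL_DEFS.update({p.name: p for p in _fam})
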