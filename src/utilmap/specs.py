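"""Named model specifications: estimator family x covariate specification.

Labels follow the mapping-study convention: ``OLS1``-``OLS6``, ``Tobit1``-
``Tobit6``, ``TPM1``-``TPM6`` and ``Beta{1-6}{a,b,c}`` where the letter is
the number of mixture components (a=1, b=2, c=3); truncated beta variants get
a ``(t)`` suffix.  The standard comparison set holds 32 models: 18 linear-
family models, 8 untruncated beta models (1a, 1b, 1c, 2a-6a) and 6 truncated
ones (1a, 2a-6a).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .models import MappingResults, fit_model_family
from .scoring import DEFAULT_SCREENED, build_design

__all__ = ["ModelSpec", "paper_model_grid", "fit_model_spec"]

_COMPONENT_LETTERS = {1: "a", 2: "b", 3: "c"}


@dataclass(frozen=True)
class ModelSpec:
    """One model in the comparison grid."""

    family: str  # OLS | TOBIT | TPM | BETA
    spec_id: int  # covariate specification 1-6
    n_components: int = 1
    truncated: bool = False
    inflate_one: bool = True
    n_starts: int = 5
    screened: tuple[str, ...] = field(default=DEFAULT_SCREENED)

    @property
    def label(self) -> str:
        if self.family == "BETA":
            letter = _COMPONENT_LETTERS.get(self.n_components, str(self.n_components))
            suffix = "(t)" if self.truncated else ""
            return f"Beta{self.spec_id}{letter}{suffix}"
        name = {"OLS": "OLS", "TOBIT": "Tobit", "TPM": "TPM"}[self.family]
        return f"{name}{self.spec_id}"

    def with_starts(self, n_starts: int) -> "ModelSpec":
        return replace(self, n_starts=n_starts)


def paper_model_grid(
    screened: tuple[str, ...] = DEFAULT_SCREENED, n_starts: int = 5
) -> list[ModelSpec]:
    """The standard 32-model comparison grid."""
    grid: list[ModelSpec] = []
    for family in ("OLS", "TOBIT", "TPM"):
        for spec_id in range(1, 7):
            grid.append(ModelSpec(family, spec_id, screened=screened))
    for truncated in (False, True):
        beta_specs = [(1, 1), (1, 2), (1, 3)] if not truncated else [(1, 1)]
        beta_specs += [(s, 1) for s in range(2, 7)]
        for spec_id, C in beta_specs:
            grid.append(
                ModelSpec(
                    "BETA",
                    spec_id,
                    n_components=C,
                    truncated=truncated,
                    n_starts=n_starts,
                    screened=screened,
                )
            )
    return grid


def fit_model_spec(cohort, spec: ModelSpec, seed: int = 0) -> MappingResults:
    """Build the design for ``spec`` and fit its family on a cohort table."""
    X = build_design(cohort, spec.spec_id, spec.screened)
    y = cohort["utility"].to_numpy(dtype=float)
    kwargs = {}
    if spec.family == "BETA":
        kwargs = dict(
            components=spec.n_components,
            truncated=spec.truncated,
            inflate_one=spec.inflate_one,
            n_starts=spec.n_starts,
            seed=seed,
        )
    return fit_model_family(spec.family, X, y, **kwargs)
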