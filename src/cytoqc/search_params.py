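"""The parameter combination searched by the validation process.

A QC module is determined by eight parameters: the batch size ``n_wsi``, the
nucleus budget ``n_nuc``, the nuclei-selection composition (ellipse variant
and spatially-even sampling), the histogram distance ``omega``, the
aggregator ``g``, the feature-selection method and its ``n_sel``, and the
seed driving the random parts of nuclei selection.  The feature-selection
pair is constrained: no selection method if and only if all features are
kept.
"""

from __future__ import annotations

from dataclasses import dataclass

from .distances import AGGREGATORS, OMEGAS

N_PARAMETERS = 8

SEL_METHODS = ("chi2", "mrmr")


@dataclass(frozen=True)
class ParamCombination:
    """One point of the validation grid (the tuple theta).

    ``intern_tau`` is None when the ellipse filter is off; ``n_sel`` is the
    string ``"all"`` exactly when ``sel_method`` is None (identity
    reduction).
    """

    n_wsi: int
    n_nuc: int
    intern_tau: float | None
    use_distrib: bool
    omega: str
    aggregator: str
    sel_method: str | None
    n_sel: int | str
    seed: int

    def __post_init__(self) -> None:
        if self.omega not in OMEGAS:
            raise ValueError(f"omega must be one of {OMEGAS}")
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"aggregator must be one of {AGGREGATORS}")
        if self.sel_method is None:
            if self.n_sel != "all":
                raise ValueError('sel_method None requires n_sel == "all"')
        else:
            if self.sel_method not in SEL_METHODS:
                raise ValueError(f"sel_method must be None or one of {SEL_METHODS}")
            if not isinstance(self.n_sel, int) or self.n_sel < 1:
                raise ValueError("n_sel must be a positive integer when selecting")
        if self.intern_tau is not None and not 0.0 < self.intern_tau <= 1.0:
            raise ValueError("intern_tau must lie in (0, 1]")

    def selection_spec(self, seed: int, use_debris_filter: bool = False):
        from .selection import SelectionSpec

        return SelectionSpec(
            n_nuc=self.n_nuc,
            seed=seed,
            intern_tau=self.intern_tau,
            use_distrib=self.use_distrib,
            use_debris_filter=use_debris_filter,
        )

    def param_values(self) -> dict[str, object]:
        """The eight named parameter values (nuclei selection is one value)."""
        return {
            "n_wsi": self.n_wsi,
            "n_nuc": self.n_nuc,
            "phi_nuc": (self.intern_tau, self.use_distrib),
            "omega": self.omega,
            "aggregator": self.aggregator,
            "sel_method": self.sel_method,
            "n_sel": self.n_sel,
            "seed": self.seed,
        }

    def with_seed(self, seed: int) -> "ParamCombination":
        from dataclasses import replace

        return replace(self, seed=seed)

    def to_dict(self) -> dict[str, object]:
        return {
            "n_wsi": self.n_wsi,
            "n_nuc": self.n_nuc,
            "intern_tau": self.intern_tau,
            "use_distrib": self.use_distrib,
            "omega": self.omega,
            "aggregator": self.aggregator,
            "sel_method": self.sel_method,
            "n_sel": self.n_sel,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamCombination":
        return cls(
            n_wsi=int(d["n_wsi"]),
            n_nuc=int(d["n_nuc"]),
            intern_tau=None if d["intern_tau"] is None else float(d["intern_tau"]),
            use_distrib=bool(d["use_distrib"]),
            omega=str(d["omega"]),
            aggregator=str(d["aggregator"]),
            sel_method=None if d["sel_method"] is None else str(d["sel_method"]),
            n_sel=d["n_sel"] if d["n_sel"] == "all" else int(d["n_sel"]),
            seed=int(d["seed"]),
        )
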