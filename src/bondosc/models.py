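"""Built-in oscillator models.

Two fixtures are constructed from printed parameter sets:

* an illustrative Goodwin-like negative-feedback chain of N enzyme-catalysed
  reaction (ECR) stages with cooperativity n, where the final product P
  inhibits the upstream activation reaction; and
* the Sel'kov glycolytic oscillator, a positive-feedback loop in which n
  copies of the product (ADP) activate the conversion of ATP.

A repressilator builder is provided as a thin loader: its 53-species wiring
and parameter table are external inputs and must be supplied as a declarative
model file.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FixtureUnavailable, ModelValidationError
from .network import LoopSpec, Network, Reaction, Species

__all__ = [
    "IllustrativeConfig",
    "SelkovConfig",
    "build_illustrative",
    "build_selkov",
    "build_repressilator",
]


@dataclass(frozen=True)
class IllustrativeConfig:
    """Parameters of the illustrative negative-feedback chain.

    ``N`` ECR stages, each A + n*E_i <-> n*E_i + E_{i+1} (the last stage
    produces P); the feedback reaction is Act + E0 <-> E1 + P, so P plays the
    inhibitor.  ``Kact`` scales the lumped source strength of the feedback
    reaction; ``kappa_rf`` is the degradation rate of every stage product;
    ``KA`` the substrate constant; ``KZf`` the (near-zero-potential)
    degradation sink constant.  All remaining constants are unity.
    """

    N: int = 3
    n: int = 2
    Kact: float = 1.0
    kappa_rf: float = 10.0
    KA: float = 100.0
    KZf: float = 1e-6

    def __post_init__(self):
        errs = []
        if not (isinstance(self.N, int) and self.N >= 1):
            errs.append(f"N must be a positive integer (got {self.N!r})")
        if not (isinstance(self.n, int) and self.n >= 1):
            errs.append(f"n must be a positive integer (got {self.n!r})")
        for name in ("Kact", "kappa_rf", "KA", "KZf"):
            if not (getattr(self, name) > 0):
                errs.append(f"{name} must be > 0 (got {getattr(self, name)!r})")
        if errs:
            raise ModelValidationError(errs)


def build_illustrative(cfg: IllustrativeConfig = IllustrativeConfig()):
    """Build the illustrative chain as (Network, LoopSpec).

    Dynamic species are E1..EN and P.  Every stage product (E2..EN and P) is
    degraded to the sink Zf at rate ``kappa_rf``; E1 is turned over only by
    the feedback reaction, whose equilibrium ties x_E1 * x_P to Kact at
    steady state.
    """
    N, n = cfg.N, cfg.n
    stage_names = [f"E{i}" for i in range(1, N + 1)]
    species = [
        Species("Act", K=cfg.Kact, amount=1.0, is_chemostat=True),
        Species("E0", K=1.0, amount=1.0, is_chemostat=True),
        Species("A", K=cfg.KA, amount=1.0, is_chemostat=True),
        Species("Zf", K=cfg.KZf, amount=1.0, is_chemostat=True),
        *[Species(name, K=1.0, amount=1.0) for name in stage_names],
        Species("P", K=1.0, amount=1.0),
    ]
    reactions = [
        Reaction("r0", kappa=1.0,
                 reactants={"Act": 1, "E0": 1}, products={"E1": 1, "P": 1}),
    ]
    chain = stage_names + ["P"]
    for i, enzyme in enumerate(stage_names):
        product = chain[i + 1]
        reactions.append(Reaction(
            f"r{i + 1}", kappa=1.0,
            reactants={"A": 1, enzyme: n}, products={enzyme: n, product: 1},
        ))
        reactions.append(Reaction(
            f"rf{product}", kappa=cfg.kappa_rf,
            reactants={product: 1}, products={"Zf": 1},
        ))
    net = Network(species, reactions)
    loop = LoopSpec(product="P", feedback_reactions=("r0",))
    loop.validate(net)
    return net, loop


@dataclass(frozen=True)
class SelkovConfig:
    """Normalized parameters of the Sel'kov glycolytic oscillator.

    ``n`` copies of the product P (ADP) bind the free enzyme E to form the
    activated complex C0; C0 binds ATP (reaction r1) to form C1 which
    releases P (reaction r2, rendered irreversible by the near-zero-potential
    chemostat Z).  ATP is supplied from the chemostat ATP0 through the slow
    reaction rs, so the steady throughput is approximately
    ``kappa_rs * K_ATP0``.  All initial amounts are unity, fixing the
    conserved enzyme moiety E + C0 + C1 at 3.
    """

    n: int = 2
    KZ: float = 1e-10
    KZf: float = 1e-10
    kappa_r0: float = 1e3
    kappa_r1: float = 1e3
    kappa_r2: float = 1e3
    kappa_rf: float = 10.0
    K_ATP0: float = 1e3
    kappa_rs: float = 6e-4

    def __post_init__(self):
        errs = []
        if not (isinstance(self.n, int) and self.n >= 1):
            errs.append(f"n must be a positive integer (got {self.n!r})")
        for name in ("KZ", "KZf", "kappa_r0", "kappa_r1", "kappa_r2",
                     "kappa_rf", "K_ATP0", "kappa_rs"):
            if not (getattr(self, name) > 0):
                errs.append(f"{name} must be > 0 (got {getattr(self, name)!r})")
        if errs:
            raise ModelValidationError(errs)


def build_selkov(cfg: SelkovConfig = SelkovConfig()):
    """Build the Sel'kov oscillator as (Network, LoopSpec).

    The feedback side of the loop is the activation reaction r0 binding
    n copies of P; the output side comprises the P-producing conversion r2
    and the degradation rf.
    """
    species = [
        Species("ATP0", K=cfg.K_ATP0, amount=1.0, is_chemostat=True),
        Species("Z", K=cfg.KZ, amount=1.0, is_chemostat=True),
        Species("Zf", K=cfg.KZf, amount=1.0, is_chemostat=True),
        Species("ATP", K=1.0, amount=1.0),
        Species("E", K=1.0, amount=1.0),
        Species("C0", K=1.0, amount=1.0),
        Species("C1", K=1.0, amount=1.0),
        Species("P", K=1.0, amount=1.0),
    ]
    reactions = [
        Reaction("rs", kappa=cfg.kappa_rs,
                 reactants={"ATP0": 1}, products={"ATP": 1}),
        Reaction("r0", kappa=cfg.kappa_r0,
                 reactants={"E": 1, "P": cfg.n}, products={"C0": 1}),
        Reaction("r1", kappa=cfg.kappa_r1,
                 reactants={"ATP": 1, "C0": 1}, products={"C1": 1}),
        Reaction("r2", kappa=cfg.kappa_r2,
                 reactants={"C1": 1}, products={"C0": 1, "P": 1, "Z": 1}),
        Reaction("rf", kappa=cfg.kappa_rf,
                 reactants={"P": 1}, products={"Zf": 1}),
    ]
    net = Network(species, reactions)
    loop = LoopSpec(product="P", feedback_reactions=("r0",))
    loop.validate(net)
    return net, loop


def build_repressilator(model_file=None):
    """Load the repressilator fixture from a declarative model file.

    The repressilator's 53-species network and parameter table are external
    inputs that are not bundled with the package.  When a model file is
    supplied it is parsed and validated like any user model; otherwise a
    :class:`FixtureUnavailable` error is raised so that callers (and test
    suites) can degrade gracefully.
    """
    if model_file is None:
        raise FixtureUnavailable(
            "repressilator parameter table not provisioned; supply a "
            "declarative model file to build this fixture"
        )
    from .modelio import load_model

    return load_model(model_file)


def builder_by_name(name: str):
    """Look up a builder and its config class by short name (CLI plumbing)."""
    table = {
        "illustrative": (build_illustrative, IllustrativeConfig),
        "selkov": (build_selkov, SelkovConfig),
    }
    try:
        return table[name]
    except KeyError:
        raise ModelValidationError(
            f"unknown builder {name!r}; choose from {sorted(table)}"
        ) from None
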