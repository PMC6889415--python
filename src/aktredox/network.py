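"""Mass-action reaction network for redox-regulated Akt membrane signalling.

The model tracks one pool of insulin receptor (inactive/active), the lipid
second messenger PIP3, one pool of NADPH oxidase (NOX, inactive/active), a
lumped ROS species, and Akt in five states: reduced/oxidized cytosolic,
reduced/oxidized plasma-membrane (PM) bound, and a single lumped
activation-loop-phosphorylated PM form (pAkt). A generic substrate pool
(Sub/pSub) reports Akt kinase output.

Mechanistic content:

* Insulin activates the receptor; the active receptor drives both PIP3
  synthesis and NOX activation, so ROS rises with growth-factor input.
* ROS oxidizes Akt (cytosolic and PM pools); oxidized Akt binds PIP3 with a
  higher on-rate than reduced Akt, reflecting the stabilised lipid-binding
  pocket of the PH-domain disulfide.
* PM-bound Akt (either redox state) is phosphorylated on its activation
  loop; only phosphorylated Akt phosphorylates the substrate pool.
* ROS also acts as an inhibitory modifier of the substrate-phosphorylation
  step (competitive-style divisor), standing in for oxidation of the Akt
  kinase domain, which attenuates catalytic output even while membrane
  recruitment and activation-loop phosphorylation rise.

Two pharmacological hooks are modelled as parameter transforms
(:func:`apply_perturbations`): the NOX inhibitor DPI divides the NOX
activation rate by ``1 + [DPI]/dpi_ki``; the antioxidant-system inhibitor
pair BCNU/AF (carmustine + auranofin) scales the ROS clearance and Akt
re-reduction rate constants by ``bcnu_af_reduction_factor``.

Units are arbitrary concentration units (totals default to 1) and minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SPECIES = [
    "Ins",
    "IR_inactive",
    "IR_active",
    "PIP3",
    "NOX_inactive",
    "NOX_active",
    "ROS",
    "Akt_red_cyt",
    "Akt_ox_cyt",
    "Akt_red_PM",
    "Akt_ox_PM",
    "pAkt_PM",
    "Sub",
    "pSub",
]

#: Conserved moieties: name -> member species. The insulin input is clamped
#: (it never appears with net stoichiometry), so it is not listed.
MOIETIES = {
    "Akt": ["Akt_red_cyt", "Akt_ox_cyt", "Akt_red_PM", "Akt_ox_PM", "pAkt_PM"],
    "IR": ["IR_inactive", "IR_active"],
    "NOX": ["NOX_inactive", "NOX_active"],
    "Sub": ["Sub", "pSub"],
}


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    rate = k * prod(reactant^stoich) * prod(modifier) / (1 + inhibitor/ki)

    ``modifiers`` multiply the rate without being consumed; ``inhibitor``
    (optional) names a species and the parameter holding its inhibition
    constant.
    """

    name: str
    reactants: dict = field(default_factory=dict)
    products: dict = field(default_factory=dict)
    modifiers: tuple = ()
    rate_param: str = ""
    inhibitor: tuple | None = None  # (species, ki_param)


def canonical_reactions() -> list[Reaction]:
    r = Reaction
    return [
        r("r0_ir_activation", {"IR_inactive": 1}, {"IR_active": 1}, ("Ins",), "k_ir_act"),
        r("r1_ir_deactivation", {"IR_active": 1}, {"IR_inactive": 1}, (), "k_ir_deact"),
        r("r2_pip3_synthesis", {}, {"PIP3": 1}, ("IR_active",), "k_pip3_synth"),
        r("r3_pip3_clearance", {"PIP3": 1}, {}, (), "k_pip3_clear"),
        r("r4_nox_activation", {"NOX_inactive": 1}, {"NOX_active": 1}, ("IR_active",), "k_nox_act"),
        r("r5_nox_deactivation", {"NOX_active": 1}, {"NOX_inactive": 1}, (), "k_nox_deact"),
        r("r6_ros_production", {}, {"ROS": 1}, ("NOX_active",), "k_ros_prod"),
        r("r7_ros_basal", {}, {"ROS": 1}, (), "k_ros_basal"),
        r("r8_ros_clearance", {"ROS": 1}, {}, (), "k_ros_clear"),
        r("r9_akt_oxidation_cyt", {"Akt_red_cyt": 1}, {"Akt_ox_cyt": 1}, ("ROS",), "k_akt_ox"),
        r("r10_akt_reduction_cyt", {"Akt_ox_cyt": 1}, {"Akt_red_cyt": 1}, (), "k_akt_red"),
        r("r11_akt_oxidation_pm", {"Akt_red_PM": 1}, {"Akt_ox_PM": 1}, ("ROS",), "k_akt_ox_pm"),
        r("r12_akt_reduction_pm", {"Akt_ox_PM": 1}, {"Akt_red_PM": 1}, (), "k_akt_red_pm"),
        r("r13_recruit_red", {"Akt_red_cyt": 1}, {"Akt_red_PM": 1}, ("PIP3",), "k_on_red"),
        r("r14_recruit_ox", {"Akt_ox_cyt": 1}, {"Akt_ox_PM": 1}, ("PIP3",), "k_on_ox"),
        r("r15_release_red", {"Akt_red_PM": 1}, {"Akt_red_cyt": 1}, (), "k_off_red"),
        r("r16_release_ox", {"Akt_ox_PM": 1}, {"Akt_ox_cyt": 1}, (), "k_off_ox"),
        r("r17_akt_phosphorylation_red", {"Akt_red_PM": 1}, {"pAkt_PM": 1}, (), "k_phos"),
        r("r18_akt_phosphorylation_ox", {"Akt_ox_PM": 1}, {"pAkt_PM": 1}, (), "k_phos_ox"),
        r("r19_akt_dephosphorylation", {"pAkt_PM": 1}, {"Akt_red_PM": 1}, (), "k_dephos"),
        r(
            "r20_substrate_phosphorylation",
            {"Sub": 1},
            {"pSub": 1},
            ("pAkt_PM",),
            "k_sub_phos",
            inhibitor=("ROS", "ros_ki"),
        ),
        r("r21_substrate_dephosphorylation", {"pSub": 1}, {"Sub": 1}, (), "k_sub_dephos"),
    ]


@dataclass
class ReactionNetwork:
    species: list[str]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names not unique")
        self._index = {s: i for i, s in enumerate(self.species)}
        n_sp, n_rx = len(self.species), len(self.reactions)
        self._net = np.zeros((n_rx, n_sp))  # products - reactants
        self._exp = np.zeros((n_rx, n_sp))  # rate-law exponents (reactants + modifiers)
        for j, rx in enumerate(self.reactions):
            for d, sign in ((rx.reactants, -1), (rx.products, +1)):
                for sp, st in d.items():
                    if int(st) != st or st <= 0:
                        raise ValueError(f"non-integer stoichiometry in {rx.name}")
                    self._net[j, self._index[sp]] += sign * st
            for sp, st in rx.reactants.items():
                self._exp[j, self._index[sp]] += st
            for sp in rx.modifiers:
                self._exp[j, self._index[sp]] += 1
        self.validate_conservation()

    @property
    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometric matrix, reactions x species."""
        return self._net.copy()

    def validate_conservation(self) -> None:
        """Check every reaction individually conserves each moiety."""
        for moiety, members in MOIETIES.items():
            idx = [self._index[s] for s in members if s in self._index]
            if not idx:
                continue
            bad = np.flatnonzero(np.abs(self._net[:, idx].sum(axis=1)) > 0)
            if bad.size:
                raise ValueError(
                    f"reaction {self.reactions[bad[0]].name!r} breaks {moiety} conservation"
                )

    def species_index(self, name: str) -> int:
        return self._index[name]

    def rate_params(self) -> list[str]:
        return [rx.rate_param for rx in self.reactions]

    def rhs(self, params: "ParameterSet"):
        """Return f(t, x) -> dx/dt for scipy integrators."""
        k = np.array([params[rx.rate_param] for rx in self.reactions])
        exp = self._exp
        netT = self._net.T
        inhib = [
            (j, self._index[rx.inhibitor[0]], params[rx.inhibitor[1]])
            for j, rx in enumerate(self.reactions)
            if rx.inhibitor is not None
        ]

        def f(t, x):
            xc = np.maximum(x, 0.0)
            with np.errstate(divide="ignore"):
                rates = k * np.prod(np.power(xc[None, :], exp), axis=1)
            for j, i_sp, ki in inhib:
                rates[j] /= 1.0 + xc[i_sp] / ki
            return netT @ rates

        return f


def build_network(config: dict | None = None) -> ReactionNetwork:
    """Build the canonical network, optionally dropping or adding reactions.

    ``config`` may contain ``drop`` (list of reaction names to remove) and
    ``extra`` (list of Reaction objects to append, each validated for moiety
    conservation). Removing a back-reaction (e.g. the pAkt
    dephosphorylation) keeps conservation valid but makes the cycle
    irreversible; a warning is emitted for that case.
    """
    import warnings

    reactions = canonical_reactions()
    if config:
        drop = set(config.get("drop", ()))
        unknown = drop - {rx.name for rx in reactions}
        if unknown:
            raise ValueError(f"unknown reactions to drop: {sorted(unknown)}")
        reactions = [rx for rx in reactions if rx.name not in drop]
        if drop:
            warnings.warn(
                f"dropped reactions {sorted(drop)}: conservation still holds but the "
                "affected cycles may be irreversible",
                stacklevel=2,
            )
        reactions.extend(config.get("extra", ()))
    return ReactionNetwork(species=list(SPECIES), reactions=reactions)


@dataclass
class ParameterSet:
    """Rate constants, conserved totals and perturbation constants.

    All entries strictly positive. Rate constants are per-minute (first
    order) or per-(unit.minute) (second order / modifier terms); totals are
    in arbitrary concentration units.
    """

    rates: dict = field(default_factory=dict)
    akt_total: float = 1.0
    ir_total: float = 1.0
    nox_total: float = 1.0
    sub_total: float = 1.0
    dpi_ki: float = 1.0
    bcnu_af_reduction_factor: float = 0.1

    def __post_init__(self) -> None:
        for name, v in self.rates.items():
            if not v > 0:
                raise ValueError(f"rate constant {name} must be > 0, got {v}")
        for name in ("akt_total", "ir_total", "nox_total", "sub_total", "dpi_ki"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.bcnu_af_reduction_factor <= 1:
            raise ValueError("bcnu_af_reduction_factor must be in (0, 1]")

    def __getitem__(self, key: str) -> float:
        if key in self.rates:
            return self.rates[key]
        return getattr(self, key)

    def with_rates(self, **updates: float) -> "ParameterSet":
        return replace(self, rates={**self.rates, **updates})

    def totals(self) -> dict:
        return {
            "Akt": self.akt_total,
            "IR": self.ir_total,
            "NOX": self.nox_total,
            "Sub": self.sub_total,
        }


#: Perturbation targets: BCNU/AF disables the glutathione/thioredoxin
#: antioxidant systems, slowing both ROS clearance and Akt re-reduction.
BCNU_AF_TARGETS = ("k_ros_clear", "k_akt_red", "k_akt_red_pm")


def apply_perturbations(
    params: ParameterSet, dpi_conc: float = 0.0, bcnu_af_on: bool = False
) -> ParameterSet:
    """Return a parameter set with DPI and/or BCNU/AF applied.

    DPI divides the NOX activation rate by ``1 + dpi_conc/dpi_ki``;
    BCNU/AF multiplies the rates in :data:`BCNU_AF_TARGETS` by
    ``bcnu_af_reduction_factor``.
    """
    if dpi_conc < 0:
        raise ValueError("dpi_conc must be >= 0")
    updates: dict[str, float] = {}
    if dpi_conc > 0:
        updates["k_nox_act"] = params["k_nox_act"] / (1.0 + dpi_conc / params.dpi_ki)
    if bcnu_af_on:
        for name in BCNU_AF_TARGETS:
            updates[name] = updates.get(name, params[name]) * params.bcnu_af_reduction_factor
    return params.with_rates(**updates) if updates else params


def reference_parameters() -> ParameterSet:
    """The package's reference parameter set (arbitrary units, minutes).

    Chosen so that the basal oxidized-Akt fraction is a fraction of a
    percent, insulin produces a ROS rise that oxidizes a few percent of
    Akt, and BCNU/AF pushes the pool majority-oxidized — the regime in
    which oxidation-enhanced recruitment raises membrane Akt and its
    activation-loop phosphorylation while kinase-domain oxidation
    suppresses substrate output.
    """
    return ParameterSet(
        rates={
            "k_ir_act": 1.0,
            "k_ir_deact": 0.2,
            "k_pip3_synth": 1.0,
            "k_pip3_clear": 2.0,
            "k_nox_act": 0.5,
            "k_nox_deact": 0.5,
            "k_ros_prod": 1.0,
            "k_ros_basal": 0.025,
            "k_ros_clear": 5.0,
            "k_akt_ox": 2.0,
            "k_akt_red": 2.0,
            "k_akt_ox_pm": 2.0,
            "k_akt_red_pm": 2.0,
            "k_on_red": 0.3,
            "k_on_ox": 15.0,
            "k_off_red": 1.0,
            "k_off_ox": 1.0,
            "k_phos": 2.0,
            "k_phos_ox": 2.0,
            "k_dephos": 1.0,
            "k_sub_phos": 2.0,
            "k_sub_dephos": 0.5,
            "ros_ki": 0.3,  # kinase-domain oxidation half-inhibition, ROS units
        },
        dpi_ki=1.0,
        bcnu_af_reduction_factor=0.1,
    )
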