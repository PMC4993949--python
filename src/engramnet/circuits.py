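"""Circuit builders: the E-I oscillator, the engram-to-oscillator encoder,
and the oscillator-to-engram router.

The oscillator is a PING-style motif: recurrently coupled excitatory (E)
and inhibitory (I) populations whose loop generates population rhythms.
The *encoder* attaches sparse engram source populations that project onto
the oscillator's E cells and — through both a mono-synaptic connection and
a di-synaptic connection via a small excitatory relay — onto its I cells;
the mono/di weight ratio is the spatial code that sets the oscillation's
frequency and power.  The *router* attaches small E-I engram readout parts
to the oscillator's E population with per-part weight pairs (w_e, w_i);
oscillatory drive at different frequencies then ignites different parts.

Numeric defaults were fixed by the calibration sweep in
:mod:`engramnet.experiments` (see ``docs/methods.md``); every value is a
plain dataclass field and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .dynamics import ConnectionSpec, PopulationSpec

__all__ = [
    "NetworkSpec",
    "EngramWeightSet",
    "OscillatorParams",
    "EngramPartParams",
    "EncoderParams",
    "RouterParams",
    "build_oscillator",
    "build_encoder",
    "build_router",
    "validate_network",
    "default_weight_sets",
    "default_ratios",
    "default_router_oscillator",
]


@dataclass
class NetworkSpec:
    """Full circuit description: populations, connections and role labels.

    ``labels`` maps functional roles (``"oscillator_E"``, ``"engram_1_E"``,
    ``"relay"`` ...) to population names, so analysis code never needs to
    know builder-internal naming.
    """

    populations: list[PopulationSpec] = field(default_factory=list)
    connections: list[ConnectionSpec] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"no population named {name!r}")

    def role(self, role: str) -> str:
        """Population name filling a functional role."""
        try:
            return self.labels[role]
        except KeyError:
            raise KeyError(f"network has no {role!r} role") from None

    def engram_part_roles(self) -> list[tuple[str, str]]:
        """Ordered (E, I) population names of the engram readout parts."""
        parts = []
        k = 1
        while f"engram_{k}_E" in self.labels:
            parts.append((self.labels[f"engram_{k}_E"], self.labels[f"engram_{k}_I"]))
            k += 1
        return parts


@dataclass(frozen=True)
class EngramWeightSet:
    """Input weights of one engram readout part.

    ``w_e``: weight (mV) from oscillator E cells onto the part's excitatory
    neurons; ``w_i``: weight onto the part's inhibitory neurons, which in
    turn provide feed-forward inhibition to the part's E cells.  The (w_e,
    w_i) pair is the spatial tag that decides which oscillation frequency
    the part follows.
    """

    index: int
    w_e: float
    w_i: float

    def __post_init__(self) -> None:
        if self.w_e < 0 or self.w_i < 0:
            raise ValueError("engram weights must be >= 0")


# --------------------------------------------------------------------------
# parameter bundles (defaults fixed by calibration)
# --------------------------------------------------------------------------

@dataclass
class OscillatorParams:
    """E-I oscillator motif parameters."""

    n_e: int = 400
    n_i: int = 100
    # neuron models
    tau_m_e: float = 10.0
    tau_m_i: float = 8.0
    v_rest: float = -70.0
    v_thresh: float = -54.0
    v_reset: float = -70.0
    t_ref_e: float = 2.0
    t_ref_i: float = 1.0
    # recurrent synapses (weight mV, probability, delay ms, tau ms)
    w_ee: float = 0.3
    w_ei: float = 0.35
    w_ie: float = 4.0
    w_ii: float = 0.9
    p_rec: float = 0.25
    delay_e: float = 1.5
    delay_i: float = 1.0
    tau_exc: float = 4.0
    tau_inh: float = 12.0
    # per-neuron Poisson background
    bg_rate_e: float = 8000.0
    bg_w_e: float = 0.15
    bg_rate_i: float = 3000.0
    bg_w_i: float = 0.1


@dataclass
class EngramPartParams:
    """One engram readout part: a small interconnected E-I pair.

    The part works as a rate-band detector on the oscillator's mean E
    output.  Its E cells integrate the oscillator through a slow excitatory
    synapse (``w_e`` sets the lower rate cutoff), while its I cells — also
    slow integrators of the same signal via ``w_i`` — veto the E cells with
    strong inhibition once the oscillator rate exceeds the upper cutoff.
    A modest recurrent E->E loop stabilizes ignition once the band matches.
    """

    n_e: int = 40
    n_i: int = 10
    tau_m_e: float = 15.0
    tau_m_i: float = 15.0
    v_rest: float = -70.0
    v_thresh: float = -54.0
    v_reset: float = -70.0
    t_ref_e: float = 2.0
    t_ref_i: float = 1.0
    # internal wiring
    w_ee: float = 0.2
    w_ei: float = 0.1
    w_ie: float = 10.0
    w_ii: float = 0.2
    p_internal: float = 0.5
    # oscillator -> part synapses; excitation is delayed relative to the
    # I pathway so the part's feed-forward inhibition can veto promptly
    p_input: float = 0.5
    tau_input_e: float = 35.0
    tau_input_i: float = 80.0
    delay_input_e: float = 4.5
    delay_input_i: float = 1.0
    tau_inh_part: float = 30.0
    delay_internal: float = 1.0
    bg_rate_e: float = 400.0
    bg_w_e: float = 0.1
    bg_rate_i: float = 200.0
    bg_w_i: float = 0.05


@dataclass
class EncoderParams:
    """Engram-source and relay wiring of the spatial-to-temporal encoder.

    The engram's output synaptic budget ``w_total`` is split by its mono/di
    ratio ``r``: a fraction ``r/(1+r)`` goes directly onto the oscillator's
    I cells (mono-synaptic), the rest onto the excitatory relay
    (di-synaptic first hop).  The relay projects onto the oscillator's I
    cells and sends collaterals onto its E cells, so the split decides how
    much of the engram's drive arrives as direct inhibition recruitment
    versus relayed excitation — which is what moves the oscillation's
    frequency and power.
    """

    n_source: int = 20
    n_relay: int = 10
    tau_m_source: float = 10.0
    tau_m_relay: float = 5.0
    t_ref: float = 2.0
    # source -> oscillator E (fixed presence drive)
    w_source_e: float = 0.6
    p_source: float = 0.8
    p_source_i: float = 0.4
    # engram output budget, split mono/di by the engram's ratio
    w_total: float = 2.0
    # relay first hop (fixed: the relay follows its source)
    w_source_relay: float = 2.5
    # relay second-hop weights per unit of di-budget
    out_split_e: float = 1.4
    out_split_i: float = 0.25
    delay_mono: float = 1.0
    delay_source_relay: float = 2.0
    delay_relay_out: float = 2.0
    tau_exc: float = 4.0
    # relay background keeps its transfer smooth near threshold
    bg_rate_relay: float = 2000.0
    bg_w_relay: float = 0.3


@dataclass
class RouterParams:
    """Input-relay wiring of the temporal-to-spatial router."""

    n_relay: int = 20
    tau_m_relay: float = 10.0
    t_ref: float = 1.0
    w_relay_i: float = 0.8
    w_relay_e: float = 1.0
    p_relay: float = 0.8
    delay_relay: float = 2.0
    tau_exc: float = 4.0
    # keeps the relay responsive across the whole drive band
    bg_rate_relay: float = 2000.0
    bg_w_relay: float = 0.25


def default_weight_sets() -> list[EngramWeightSet]:
    """Calibrated (w_e, w_i) pairs: parts 1/2/3 follow the low/medium/high
    drive bands (about 19, 25 and 32 Hz) respectively."""
    return [
        EngramWeightSet(1, w_e=0.32, w_i=0.22),
        EngramWeightSet(2, w_e=0.24, w_i=0.17),
        EngramWeightSet(3, w_e=0.19, w_i=0.13),
    ]


def default_ratios() -> list[float]:
    """Calibrated mono/di weight ratios of the default three-engram encoder.

    Descending relay share: engram 1 (ratio 8) drives the slowest rhythm
    (~19 Hz), engram 3 (ratio 0.1) the fastest (~32 Hz)."""
    return [8.0, 1.0, 0.1]


def default_router_oscillator() -> OscillatorParams:
    """Oscillator operating point used by the router.

    Softer recurrence and faster inhibition than the encoder default: the
    E population is quiescent without drive and follows the relay-gated
    rhythm of Input1 one volley per cycle across the whole band."""
    return OscillatorParams(
        w_ee=0.3, w_ei=0.35, w_ie=2.0, w_ii=0.9, tau_inh=8.0,
        bg_rate_e=8000.0, bg_w_e=0.15, bg_rate_i=3000.0, bg_w_i=0.1,
    )


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def _oscillator_parts(params: OscillatorParams, prefix: str = "osc"):
    e_name, i_name = f"{prefix}_E", f"{prefix}_I"
    pops = [
        PopulationSpec(
            name=e_name,
            size=params.n_e,
            cell_type="excitatory",
            tau_m=params.tau_m_e,
            v_rest=params.v_rest,
            v_thresh=params.v_thresh,
            v_reset=params.v_reset,
            t_ref=params.t_ref_e,
            background_rate=params.bg_rate_e,
            background_weight=params.bg_w_e,
        ),
        PopulationSpec(
            name=i_name,
            size=params.n_i,
            cell_type="inhibitory",
            tau_m=params.tau_m_i,
            v_rest=params.v_rest,
            v_thresh=params.v_thresh,
            v_reset=params.v_reset,
            t_ref=params.t_ref_i,
            background_rate=params.bg_rate_i,
            background_weight=params.bg_w_i,
        ),
    ]
    conns = [
        ConnectionSpec(e_name, e_name, params.w_ee, params.p_rec,
                       params.delay_e, params.tau_exc),
        ConnectionSpec(e_name, i_name, params.w_ei, params.p_rec,
                       params.delay_e, params.tau_exc),
        ConnectionSpec(i_name, e_name, params.w_ie, params.p_rec,
                       params.delay_i, params.tau_inh),
        ConnectionSpec(i_name, i_name, params.w_ii, params.p_rec,
                       params.delay_i, params.tau_inh),
    ]
    labels = {"oscillator_E": e_name, "oscillator_I": i_name}
    return pops, conns, labels


def build_oscillator(params: OscillatorParams | None = None) -> NetworkSpec:
    """A validated E-I oscillator with all four recurrent connection classes
    (E->E, E->I, I->E, I->I).  Under sustained drive the default parameters
    produce a single dominant population rhythm above 20 Hz."""
    params = params or OscillatorParams()
    pops, conns, labels = _oscillator_parts(params)
    net = NetworkSpec(populations=pops, connections=conns, labels=labels)
    _raise_on_violations(net)
    return net


def build_encoder(
    n_engrams: int,
    ratios: Sequence[float] | None = None,
    osc_params: OscillatorParams | None = None,
    enc_params: EncoderParams | None = None,
) -> NetworkSpec:
    """Engram-to-oscillator encoder.

    Each engram source population projects onto the oscillator's E cells
    and onto its I cells twice: directly (mono-synaptic) and through a
    dedicated excitatory relay (di-synaptic).  With the engram's total
    output budget ``Q`` fixed, its ratio ``r`` (mono/di) splits it as
    ``w_mono = Q r/(1+r)`` onto I and ``w_di = Q/(1+r)`` onto the relay;
    distinct ratios give distinct oscillation frequencies and powers.
    """
    if n_engrams < 1:
        raise ValueError("n_engrams must be >= 1")
    ratios = list(default_ratios()[:n_engrams] if ratios is None else ratios)
    if len(ratios) != n_engrams:
        raise ValueError("need one mono/di ratio per engram")
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be >= 0")
    if len(set(ratios)) != len(ratios):
        raise ValueError(
            "duplicate mono/di ratios: engrams would be indistinguishable"
        )
    osc = osc_params or OscillatorParams()
    enc = enc_params or EncoderParams()
    pops, conns, labels = _oscillator_parts(osc)
    e_name, i_name = labels["oscillator_E"], labels["oscillator_I"]

    for k, ratio in enumerate(ratios, start=1):
        src, relay = f"source_{k}", f"relay_{k}"
        pops.append(
            PopulationSpec(
                name=src, size=enc.n_source, cell_type="excitatory",
                tau_m=enc.tau_m_source, t_ref=enc.t_ref,
            )
        )
        pops.append(
            PopulationSpec(
                name=relay, size=enc.n_relay, cell_type="excitatory",
                tau_m=enc.tau_m_relay, t_ref=enc.t_ref,
                background_rate=enc.bg_rate_relay,
                background_weight=enc.bg_w_relay,
            )
        )
        w_mono = enc.w_total * ratio / (1.0 + ratio)
        w_di = enc.w_total / (1.0 + ratio)
        conns.append(
            ConnectionSpec(src, e_name, enc.w_source_e, enc.p_source,
                           enc.delay_mono, enc.tau_exc)
        )
        if w_mono > 0:
            conns.append(
                ConnectionSpec(src, i_name, w_mono, enc.p_source_i,
                               enc.delay_mono, enc.tau_exc)
            )
        conns.append(
            ConnectionSpec(src, relay, enc.w_source_relay, enc.p_source,
                           enc.delay_source_relay, enc.tau_exc)
        )
        if w_di * enc.out_split_i > 0:
            conns.append(
                ConnectionSpec(relay, i_name, w_di * enc.out_split_i,
                               enc.p_source, enc.delay_relay_out, enc.tau_exc)
            )
        if w_di * enc.out_split_e > 0:
            conns.append(
                ConnectionSpec(relay, e_name, w_di * enc.out_split_e,
                               enc.p_source, enc.delay_relay_out, enc.tau_exc)
            )
        labels[f"engram_source_{k}"] = src
        labels[f"relay_{k}"] = relay
    net = NetworkSpec(populations=pops, connections=conns, labels=labels)
    _raise_on_violations(net)
    return net


def build_router(
    osc_params: OscillatorParams | None = None,
    weight_sets: Sequence[EngramWeightSet] | None = None,
    part_params: EngramPartParams | None = None,
    router_params: RouterParams | None = None,
) -> NetworkSpec:
    """Oscillator-to-engram router.

    The oscillator E population projects onto every engram part's E neurons
    (weight ``w_e``) and I neurons (weight ``w_i``); each part is itself a
    small interconnected E-I pair.  An excitatory input relay carries the
    di-synaptic oscillatory drive onto the oscillator's I cells.
    """
    osc = osc_params or default_router_oscillator()
    sets = list(default_weight_sets() if weight_sets is None else weight_sets)
    if not sets:
        raise ValueError("need at least one engram weight set")
    pairs = [(ws.w_e, ws.w_i) for ws in sets]
    if len(set(pairs)) != len(pairs):
        raise ValueError(
            "duplicate engram weight sets: parts would be indistinguishable"
        )
    part = part_params or EngramPartParams()
    rtr = router_params or RouterParams()

    pops, conns, labels = _oscillator_parts(osc)
    e_name, i_name = labels["oscillator_E"], labels["oscillator_I"]

    relay = "input_relay"
    pops.append(
        PopulationSpec(
            name=relay, size=rtr.n_relay, cell_type="excitatory",
            tau_m=rtr.tau_m_relay, t_ref=rtr.t_ref,
            background_rate=rtr.bg_rate_relay,
            background_weight=rtr.bg_w_relay,
        )
    )
    conns.append(
        ConnectionSpec(relay, i_name, rtr.w_relay_i, rtr.p_relay,
                       rtr.delay_relay, rtr.tau_exc)
    )
    if rtr.w_relay_e > 0:
        conns.append(
            ConnectionSpec(relay, e_name, rtr.w_relay_e, rtr.p_relay,
                           rtr.delay_relay, rtr.tau_exc)
        )
    labels["relay"] = relay

    for k, ws in enumerate(sets, start=1):
        pe, pi = f"engram_{k}_E", f"engram_{k}_I"
        pops.append(
            PopulationSpec(
                name=pe, size=part.n_e, cell_type="excitatory",
                tau_m=part.tau_m_e, v_rest=part.v_rest,
                v_thresh=part.v_thresh, v_reset=part.v_reset,
                t_ref=part.t_ref_e, background_rate=part.bg_rate_e,
                background_weight=part.bg_w_e,
            )
        )
        pops.append(
            PopulationSpec(
                name=pi, size=part.n_i, cell_type="inhibitory",
                tau_m=part.tau_m_i, v_rest=part.v_rest,
                v_thresh=part.v_thresh, v_reset=part.v_reset,
                t_ref=part.t_ref_i, background_rate=part.bg_rate_i,
                background_weight=part.bg_w_i,
            )
        )
        if ws.w_e > 0:
            conns.append(
                ConnectionSpec(e_name, pe, ws.w_e, part.p_input,
                               part.delay_input_e, part.tau_input_e)
            )
        if ws.w_i > 0:
            conns.append(
                ConnectionSpec(e_name, pi, ws.w_i, part.p_input,
                               part.delay_input_i, part.tau_input_i)
            )
        conns.extend(
            [
                ConnectionSpec(pe, pe, part.w_ee, part.p_internal,
                               part.delay_internal, part.tau_input_e),
                ConnectionSpec(pe, pi, part.w_ei, part.p_internal,
                               part.delay_internal, 4.0),
                ConnectionSpec(pi, pe, part.w_ie, part.p_internal,
                               part.delay_internal, part.tau_inh_part),
                ConnectionSpec(pi, pi, part.w_ii, part.p_internal,
                               part.delay_internal, part.tau_inh_part),
            ]
        )
        labels[f"engram_{k}_E"] = pe
        labels[f"engram_{k}_I"] = pi
    net = NetworkSpec(populations=pops, connections=conns, labels=labels)
    _raise_on_violations(net)
    return net


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_network(network: NetworkSpec, dt: float = 0.1) -> list[str]:
    """Collect structural violations; an empty list means the network is
    valid.  Checks reference integrity, Dale's law, synaptic delays against
    the integration step, and role-label completeness."""
    violations: list[str] = []
    seen: set[str] = set()
    for p in network.populations:
        if p.name in seen:
            violations.append(f"duplicate population name {p.name!r}")
        seen.add(p.name)
    by_name = {p.name: p for p in network.populations}

    for c in network.connections:
        if c.source not in by_name:
            violations.append(
                f"connection {c.source}->{c.target}: unknown source population"
            )
        if c.target not in by_name:
            violations.append(
                f"connection {c.source}->{c.target}: unknown target population"
            )
        if c.weight < 0:
            violations.append(
                f"connection {c.source}->{c.target}: negative weight violates "
                "Dale's law sign convention"
            )
        if c.delay < dt:
            violations.append(
                f"connection {c.source}->{c.target}: delay {c.delay} ms below "
                f"the integration step {dt} ms"
            )

    for role, name in network.labels.items():
        if name not in by_name:
            violations.append(f"label {role!r} names unknown population {name!r}")

    if "oscillator_E" in network.labels and "oscillator_I" in network.labels:
        e = network.labels["oscillator_E"]
        i = network.labels["oscillator_I"]
        if e in by_name and by_name[e].cell_type != "excitatory":
            violations.append("oscillator_E role is not an excitatory population")
        if i in by_name and by_name[i].cell_type != "inhibitory":
            violations.append("oscillator_I role is not an inhibitory population")
        have = {(c.source, c.target) for c in network.connections}
        for pair, tag in [
            ((e, e), "E->E"), ((e, i), "E->I"), ((i, e), "I->E"), ((i, i), "I->I"),
        ]:
            if pair not in have:
                violations.append(
                    f"oscillator is missing its recurrent {tag} connection"
                )
    elif "oscillator_E" in network.labels or "oscillator_I" in network.labels:
        violations.append("oscillator role set must contain both an E and an I")
    return violations


def _raise_on_violations(net: NetworkSpec) -> None:
    violations = validate_network(net)
    if violations:
        raise ValueError("invalid network: " + "; ".join(violations))
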