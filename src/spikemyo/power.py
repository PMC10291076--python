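"""AC/MAC inference-power model.

Energy is counted in relative units per arithmetic operation: an accumulate
(AC) costs 0.1 and a multiply-accumulate (MAC) costs 3.1, reflecting the
~31x power ratio of 32-bit floating-point MAC over AC on 45 nm CMOS.
Spiking layers move binary events, so their synaptic work scales with the
spike release rate (SRR) and costs ACs, while the per-neuron state updates
cost a fixed number of MACs per time step; conventional LSTM/CNN layers pay
MACs for every weight.  The formulas are implemented verbatim as an
idealised operation count (e.g. the CNN FC term uses H*W*C2 regardless of
the realised post-pooling size) — the model is a comparator, not a
micro-architecture simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AC_COST",
    "MAC_COST",
    "PowerReport",
    "encoding_power",
    "snn_power",
    "lstm_power",
    "cnn_power",
    "snn_total_power",
]

AC_COST = 0.1
MAC_COST = 3.1


@dataclass(frozen=True)
class PowerReport:
    """Named component -> relative energy; total is their sum."""

    components: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    def __add__(self, other: "PowerReport") -> "PowerReport":
        merged = dict(self.components)
        for k, v in other.components.items():
            merged[k] = merged.get(k, 0.0) + v
        return PowerReport(components=merged)


def encoding_power(T: int, ch: int) -> PowerReport:
    """Spike-encoding cost: the per-channel mean and standard deviation of
    the T signal differences dominate."""
    mean_term = (T * AC_COST + MAC_COST) * ch
    std_term = (T * AC_COST + (T + 1) * MAC_COST) * ch
    return PowerReport({"encoding_mean": mean_term, "encoding_std": std_term})


def snn_power(T: int, i: int, h: int, o: int,
              srr1: float, srr2: float) -> PowerReport:
    """Two spiking layers: event-driven synaptic ACs (scaled by the input and
    hidden-layer SRRs) plus 2 MACs per neuron per step for the U/I updates."""
    if not (0 <= srr1 <= 1 and 0 <= srr2 <= 1):
        raise ValueError("SRR values must lie in [0, 1]")
    layer1 = T * (srr1 * i * h * AC_COST + 2 * h * MAC_COST)
    layer2 = T * (srr2 * o * h * AC_COST + 2 * o * MAC_COST)
    return PowerReport({"snn_layer1": layer1, "snn_layer2": layer2})


def lstm_power(T: int, i: int, h: int, o: int) -> PowerReport:
    """Four-gate LSTM layer plus fully-connected readout, all MACs."""
    lstm_term = T * (4 * (i * h + h * h) * MAC_COST)
    fc_term = T * h * o * MAC_COST
    return PowerReport({"lstm_layer": lstm_term, "fc": fc_term})


def cnn_power(k1: int, k2: int, H: int, W: int, C: int,
              C1: int, C2: int, o: int) -> PowerReport:
    """Two convolutional layers plus fully-connected readout, all MACs."""
    conv_term = (k1 * k2 * H * W * (C * C1 + C1 * C2)) * MAC_COST
    fc_term = MAC_COST * H * W * C2 * o
    return PowerReport({"conv_layers": conv_term, "fc": fc_term})


def snn_total_power(T: int, ch: int, i: int, h: int, o: int,
                    srr1: float, srr2: float) -> PowerReport:
    """Encoding + network, the full event-driven inference cost."""
    if ch != i:
        raise ValueError("encoder channel count must equal SNN input count")
    return encoding_power(T, ch) + snn_power(T, i, h, o, srr1, srr2)
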