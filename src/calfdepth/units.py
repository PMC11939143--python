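"""Unit conversions used when reporting body weight."""

LB_TO_KG = 0.45359237


def lb_to_kg(pounds: float) -> float:
    return pounds * LB_TO_KG


def kg_to_lb(kilograms: float) -> float:
    return kilograms / LB_TO_KG
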