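"""Published per-locus summary columns of the 30-locus DIPplex panel in the
Dongxiang population sample (n = 169): insertion frequency, MP, PIC, PE,
TPI, He.  Used as the reference surface for the forensic statistics and as
input to the arbitrary-precision panel-combination oracle.
"""

N_INDIVIDUALS = 169

# locus: (p_insertion, MP, PIC, PE, TPI, He)
PANEL_ROWS = {
    "HLD 77": (0.4586, 0.3481, 0.3733, 0.1266, 0.8622, 0.4980),
    "HLD 45": (0.6746, 0.4072, 0.3427, 0.1306, 0.8711, 0.4404),
    "HLD 131": (0.4320, 0.3672, 0.3703, 0.1560, 0.9286, 0.4922),
    "HLD 70": (0.5680, 0.3828, 0.3703, 0.1849, 0.9941, 0.4922),
    "HLD 6": (0.4911, 0.3681, 0.3749, 0.1749, 0.9713, 0.5013),
    "HLD 111": (0.1598, 0.5705, 0.2324, 0.0527, 0.6870, 0.2693),
    "HLD 58": (0.3905, 0.3737, 0.3627, 0.1387, 0.8895, 0.4774),
    "HLD 56": (0.5799, 0.3708, 0.3685, 0.1560, 0.9286, 0.4887),
    "HLD 118": (0.8550, 0.6140, 0.2172, 0.0285, 0.6213, 0.2486),
    "HLD 92": (0.3669, 0.3852, 0.3566, 0.1387, 0.8895, 0.4659),
    "HLD 93": (0.5473, 0.3939, 0.3727, 0.2119, 1.0563, 0.4970),
    "HLD 99": (0.8462, 0.5766, 0.2265, 0.0572, 0.6983, 0.2611),
    "HLD 88": (0.5266, 0.3750, 0.3743, 0.1849, 0.9941, 0.5001),
    "HLD 101": (0.4734, 0.3693, 0.3743, 0.1749, 0.9713, 0.5001),
    "HLD 67": (0.5651, 0.3738, 0.3707, 0.1700, 0.9602, 0.4930),
    "HLD 83": (0.3905, 0.3820, 0.3627, 0.1560, 0.9286, 0.4774),
    "HLD 114": (0.3077, 0.4419, 0.3353, 0.1749, 0.9713, 0.4273),
    "HLD 48": (0.3994, 0.3760, 0.3647, 0.1515, 0.9185, 0.4812),
    "HLD 124": (0.5947, 0.4073, 0.3659, 0.2119, 1.0563, 0.4835),
    "HLD 122": (0.3254, 0.4041, 0.3427, 0.1228, 0.8535, 0.4404),
    "HLD 125": (0.4527, 0.4334, 0.3727, 0.2742, 1.2071, 0.4970),
    "HLD 64": (0.7988, 0.5119, 0.2698, 0.0773, 0.7478, 0.3224),
    "HLD 81": (0.7633, 0.4723, 0.2961, 0.0719, 0.7348, 0.3624),
    "HLD 136": (0.5148, 0.3864, 0.3748, 0.2063, 1.0432, 0.5010),
    "HLD 133": (0.3432, 0.4420, 0.3492, 0.2176, 1.0696, 0.4522),
    "HLD 97": (0.3669, 0.3982, 0.3566, 0.1652, 0.9494, 0.4659),
    "HLD 40": (0.6272, 0.4003, 0.3583, 0.1749, 0.9713, 0.4690),
    "HLD 128": (0.3728, 0.3860, 0.3583, 0.1472, 0.9086, 0.4690),
    "HLD 39": (0.2041, 0.5095, 0.2721, 0.0919, 0.7824, 0.3259),
    "HLD 84": (0.6746, 0.4189, 0.3427, 0.1560, 0.9286, 0.4404),
}

# The four rows whose cells were hand-verified against the stated formulas;
# genotype counts below follow by inverting (p, TPI, n).
VERIFIED_ROWS = ("HLD 77", "HLD 6", "HLD 111", "HLD 118")
VERIFIED_COUNTS = {
    "HLD 77": (42, 71, 56),
    "HLD 6": (42, 82, 45),
    "HLD 111": (4, 46, 119),
    "HLD 118": (128, 33, 8),
}
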