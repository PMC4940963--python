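"""Independent straight-from-the-definitions re-implementation of the
per-child classification rules, written as explicit nested conditionals
with hard-coded schedule numbers.  Shares no code with the package; used
only to audit it."""

FIC_DOSES = ["BCG", "OPV1", "OPV2", "OPV3", "PENTA1", "PENTA2", "PENTA3", "MV"]

# label -> (recommended age, early margin, delay margin)
WINDOWS = {
    "BCG": (0, 4, 14),
    "OPV0": (0, 4, 14),
    "OPV1": (42, 4, 14), "OPV2": (70, 4, 14), "OPV3": (98, 4, 14),
    "PENTA1": (42, 4, 14), "PENTA2": (70, 4, 14), "PENTA3": (98, 4, 14),
    "PCV1": (42, 4, 14), "PCV2": (70, 4, 14), "PCV3": (98, 4, 14),
    "MV": (274, 4, 30),
}


def ages_of(child):
    return {e.antigen: (e.date - child.dob).days for e in child.events}


def oracle_fic(child, cutoff=365):
    """(fic, missing set, fic_after_cutoff) by checking each dose in turn."""
    ages = ages_of(child)
    missing = set()
    late = False
    for dose in FIC_DOSES:
        if dose not in ages:
            missing.add(dose)
        else:
            if ages[dose] > cutoff:
                late = True
    if len(missing) == 0 and not late:
        return True, missing, False
    if len(missing) == 0 and late:
        return False, missing, True
    return False, missing, False


def oracle_timeliness(child):
    """label -> early/timely/delayed/missing from the literal window rules."""
    ages = ages_of(child)
    out = {}
    for dose, (rec, early_m, delay_m) in WINDOWS.items():
        if dose not in ages:
            out[dose] = "missing"
        else:
            a = ages[dose]
            if rec - a > early_m:
                out[dose] = "early"
            elif a - rec > delay_m:
                out[dose] = "delayed"
            else:
                out[dose] = "timely"
    return out


def oracle_flags(child, cutoff=365):
    """(late_bcg, penta_opv_split, penta_after_mv) among doses by the cutoff."""
    ages = {k: v for k, v in ages_of(child).items() if v <= cutoff}

    late_bcg = False
    if "BCG" in ages:
        for dose, a in ages.items():
            if dose == "BCG" or dose == "OPV0":
                continue
            if ages["BCG"] >= a:
                late_bcg = True

    split = False
    for k in (1, 2, 3):
        if f"PENTA{k}" in ages:
            if f"OPV{k}" in ages:
                if ages[f"PENTA{k}"] != ages[f"OPV{k}"]:
                    split = True

    penta_after_mv = False
    if "MV" in ages:
        for k in (1, 2, 3):
            if f"PENTA{k}" in ages:
                if ages[f"PENTA{k}"] >= ages["MV"]:
                    penta_after_mv = True

    return late_bcg, split, penta_after_mv
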