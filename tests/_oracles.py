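"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the implementation's regular expressions and
library calls: the date and age oracles are explicit step-by-step rule
checkers, and the Wilson oracle is the closed-form score interval written
out directly.
"""

import math

from scipy.stats import norm

MONTHS = ("January", "February", "March", "April", "May", "June", "July",
          "August", "September", "October", "November", "December")
AGE_UNITS = ("Year", "Years", "Month", "Months", "Week", "Weeks",
             "Day", "Days", "Hour", "Hours", "Minute", "Minutes")


def date_acceptable(text: str) -> bool:
    """Explicit rule checker for the registry date grammar."""
    if text == "Unknown":
        return True
    head, sep, year = text.partition(", ")
    if not sep:
        return False
    if len(year) != 4 or not year.isdigit() or year[0] not in "12":
        return False
    parts = head.split(" ")
    if len(parts) == 1:
        return parts[0] in MONTHS
    if len(parts) == 2:
        month, day = parts
        if month not in MONTHS:
            return False
        if not day.isdigit() or day != str(int(day)):  # no leading zeros
            return False
        return 1 <= int(day) <= 31
    return False


def age_acceptable(text: str) -> bool:
    """Explicit rule checker for the registry age grammar."""
    if text == "N/A":
        return True
    parts = text.split(" ")
    if len(parts) != 2:
        return False
    magnitude, unit = parts
    if not magnitude.isdigit() or magnitude != str(int(magnitude)):
        return False
    return int(magnitude) >= 1 and unit in AGE_UNITS


def date_domain() -> list[str]:
    """Exhaustive small domain for grammar-equivalence checks."""
    candidates = ["Unknown", "unknown", "", " ", "January", "2004",
                  "January 2004", "January  3, 2004", "Jan 3, 2004",
                  "January 3, 04", "January 3, 20041", "March,2005",
                  "March , 2005", "January 3, 0999", "January 3, 3000"]
    months = MONTHS + ("Januar", "march", "December ")
    for month in months:
        for year in ("1999", "2017", "0999", "999", "20170"):
            candidates.append(f"{month}, {year}")
            for day in [str(d) for d in range(0, 33)] + ["03", "1 ", "3.5"]:
                candidates.append(f"{month} {day}, {year}")
    return candidates


def age_domain() -> list[str]:
    candidates = ["N/A", "N/a", "", "Years", "2Years", "2  Years",
                  "2 years", "-1 Years", "1.5 Years", "two Years"]
    for mag in ["0", "1", "9", "10", "01", "007", "120", "99999"]:
        for unit in AGE_UNITS + ("Yearss", "Min", "Decades"):
            candidates.append(f"{mag} {unit}")
    return candidates


def wilson_interval(successes: int, trials: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Closed-form Wilson score interval."""
    z = norm.ppf((1 + confidence) / 2)
    p = successes / trials
    denom = 1 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    half = (z * math.sqrt(p * (1 - p) / trials
                          + z * z / (4 * trials * trials))) / denom
    return center - half, center + half
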