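"""Select the incident-transplant cohort and write the attrition flow.

Applies the six eligibility steps (enrolment window, single organ, 2-year
transplant washout, registered+alive through day 30, 180-day L04 washout,
maintenance dispensing in the 30-day landmark) and prints the flow chart.
"""

import txclaims as tx

from common import build_study, outdir, parse_args


def main() -> None:
    args = parse_args(__doc__)
    study = build_study(args.seed, args.n)
    out = outdir("cohort")

    cohort, attrition = study["cohort"], study["attrition"]
    cohort.to_csv(out / "cohort.csv", index=False)
    attrition.to_json(out / "attrition.json")
    (out / "attrition.txt").write_text(attrition.to_text())

    print(attrition.to_text())
    print(f"\ninclusion proportion: "
          f"{tx.attrition_proportion(attrition)}% "
          f"({attrition.final}/{attrition.initial})")
    shares = cohort["organ"].value_counts()
    for organ, n in shares.items():
        print(f"  {organ:10s} {n:5d} ({tx.share_percent(n, len(cohort))}%)")


if __name__ == "__main__":
    main()
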