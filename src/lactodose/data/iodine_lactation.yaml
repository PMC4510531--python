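# Transfer-rate registry for the lactating-adult iodine model.
#
# Rates are 1/day on the compartment graph: HRTM (respiratory) -> blood and
# alimentary tract; HATM (alimentary) -> blood via the small intestine;
# systemic iodine kinetics during lactation with salivary/gastric secretion
# back to the gut, urinary excretion, and a breast -> breast-milk pathway.
#
# Numeric values are a reconstruction from the ICRP model family (HRTM
# clearance per ICRP 66, alimentary transit per ICRP 100 adult female,
# systemic iodine kinetics per the classic ICRP adult iodine model arranged on
# the ICRP 95 lactation structure).  Fast oral/oesophageal transit is capped
# at 720/d so the graph is integrable at the reference 0.001-day fixed step;
# transit remains >> every other rate, so downstream quantities are
# insensitive to the cap.
version: 1
half_life_days: 8.0252

compartments:
  [ET, BB, bb, AI, LN, OC, OE, ST, SI, RC, LC, RS, FA, SA, GS,
   IT, OIT, OIO, IO, OV, UB, UR, BR, BM, blood, EN]

sinks: [UR, FA, BM, EN]

transfers:
  # --- respiratory tract (HRTM) mechanical clearance -----------------------
  - {src: ET, dst: OE, rate: 100.0, note: "ICRP 66: ET2 swallowed to alimentary tract, 100/d"}
  - {src: BB, dst: ET, rate: 10.0, note: "ICRP 66: BB1 fast mucociliary escalator, 10/d"}
  - {src: bb, dst: BB, rate: 2.0, note: "ICRP 66: bb1 fast mucociliary escalator, 2/d"}
  - {src: AI, dst: bb, rate: 0.0066, note: "ICRP 66: deposition-weighted AI1-AI3 particle transport"}
  - {src: BB, dst: LN, rate: 0.00007, note: "ICRP 66: sequestered bronchial fraction to thoracic lymph nodes"}
  - {src: bb, dst: LN, rate: 0.00007, note: "ICRP 66: sequestered bronchiolar fraction to thoracic lymph nodes"}
  - {src: AI, dst: LN, rate: 0.00002, note: "ICRP 66: AI3 to thoracic lymph nodes"}
  # --- respiratory dissolution/absorption (Type F and SR-1 vapour) ---------
  - {src: ET, dst: blood, rate: 100.0, note: "Type F / SR-1 rapid dissolution-absorption, 100/d"}
  - {src: BB, dst: blood, rate: 100.0, note: "Type F / SR-1 rapid dissolution-absorption, 100/d"}
  - {src: bb, dst: blood, rate: 100.0, note: "Type F / SR-1 rapid dissolution-absorption, 100/d"}
  - {src: AI, dst: blood, rate: 100.0, note: "Type F / SR-1 rapid dissolution-absorption, 100/d"}
  - {src: LN, dst: blood, rate: 100.0, note: "Type F dissolution in lymph nodes, 100/d"}
  # --- alimentary tract (HATM, adult female) -------------------------------
  - {src: OC, dst: OE, rate: 720.0, note: "ICRP 100 oral transit (capped fast-transit rate)"}
  - {src: OE, dst: ST, rate: 720.0, note: "ICRP 100 oesophageal transit (capped fast-transit rate)"}
  - {src: ST, dst: SI, rate: 20.57, note: "ICRP 100: gastric emptying, 70 min total diet"}
  - {src: SI, dst: blood, rate: 6.0, note: "4-h small-intestine transit; iodine fA = 1 so all SI outflow is absorbed"}
  - {src: RC, dst: LC, rate: 1.5, note: "ICRP 100 adult female right colon, 16 h"}
  - {src: LC, dst: RS, rate: 1.5, note: "ICRP 100 adult female left colon, 16 h"}
  - {src: RS, dst: FA, rate: 1.5, note: "ICRP 100 adult female rectosigmoid, 16 h"}
  # --- systemic iodine during lactation ------------------------------------
  - {src: blood, dst: IT, rate: 0.831, note: "iodide uptake by thyroid (classic adult iodine kinetics)"}
  - {src: blood, dst: UB, rate: 1.29, note: "renal clearance of circulating iodide"}
  - {src: blood, dst: SA, rate: 0.139, note: "salivary secretion of iodide"}
  - {src: blood, dst: GS, rate: 0.208, note: "gastric secretion of iodide"}
  - {src: blood, dst: IO, rate: 0.277, note: "iodide exchange with other organs and tissues"}
  - {src: blood, dst: OV, rate: 0.0014, note: "iodide exchange with ovaries (small pool)"}
  - {src: blood, dst: BR, rate: 0.347, note: "iodide uptake by lactating breast (mammary NIS transport)"}
  - {src: IT, dst: OIT, rate: 8.32, note: "organification of trapped thyroid iodide, ~2 h"}
  - {src: OIT, dst: OIO, rate: 0.00866, note: "thyroid hormone secretion, 80-d organic retention"}
  - {src: OIO, dst: blood, rate: 0.0462, note: "peripheral deiodination; 80% of organic turnover recycled as iodide"}
  - {src: OIO, dst: RC, rate: 0.0115, note: "biliary/faecal loss; 20% of organic turnover"}
  - {src: IO, dst: blood, rate: 1.39, note: "tissue iodide return, 12 h"}
  - {src: OV, dst: blood, rate: 1.39, note: "ovarian iodide return, 12 h"}
  - {src: SA, dst: OC, rate: 50.0, note: "saliva flow into oral cavity"}
  - {src: GS, dst: ST, rate: 50.0, note: "gastric juice flow into stomach"}
  - {src: UB, dst: UR, rate: 12.0, note: "urinary bladder voiding"}
  - {src: BR, dst: BM, rate: 1.386, note: "secretion of breast iodide into milk, 12 h"}
  - {src: BR, dst: blood, rate: 0.462, note: "return of breast iodide to circulation"}

# Fraction of inhaled/ingested activity entering each compartment, per route.
# The particulate ET1 (anterior nares) deposit never reaches systemic
# circulation and is assigned directly to the environment sink EN; the
# remainder to 1.0 is exhaled and never enters the system.
deposition:
  ingestion:
    OC: 1.0
  vapour_sr1:
    ET: 0.10
    BB: 0.20
    bb: 0.30
    AI: 0.40
  particulate_amad1:
    EN: 0.165   # ET1 deposit (anterior nares, cleared externally)
    ET: 0.211   # ET2
    BB: 0.0124
    bb: 0.0165
    AI: 0.107
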