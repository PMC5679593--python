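# SYNTHETIC per-item unit costs (2016 GBP) for event-mode costing demos.
# The study's per-item cost tables are not public; these stand-in values
# are round placeholder figures and must be replaced with payer tariffs
# for any real costing run.
country: UK
currency: GBP
ed_bed_hour: 50.0
item_costs:
  blood draw: 5.0
  ECG: 30.0
  CT scan: 120.0
  MRI scan: 200.0
  echocardiography: 80.0
  invasive angiography: 1200.0
  CABG: 9000.0
  PTCA: 3000.0
  stent: 2500.0
  outpatient stress test: 90.0
  alt_dx_inpatient: 1500.0
  ami_inpatient_readmission: 2500.0
  ami_treatment_misdiagnosis: 2000.0
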