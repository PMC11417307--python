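name: tls_smq_broad_synthetic
scope: smq_broad
# SYNTHETIC placeholder for the licensed MedDRA "Tumour lysis syndrome"
# SMQ broad PT list (39 terms).  The true SMQ requires a MedDRA license
# and is not redistributable; replace this file with your own export for
# licensed analyses.  The 39 PTs below cover the laboratory, renal,
# cardiac and neuromuscular manifestations characteristic of TLS.
Tumour lysis syndrome
Hyperuricaemia
Hyperkalaemia
Hyperphosphataemia
Hypocalcaemia
Blood uric acid increased
Blood potassium increased
Blood phosphorus increased
Blood calcium decreased
Acute kidney injury
Renal failure
Renal impairment
Blood creatinine increased
Blood urea increased
Glomerular filtration rate decreased
Anuria
Oliguria
Urine output decreased
Azotaemia
Urate nephropathy
Nephropathy toxic
Renal tubular necrosis
Nephrocalcinosis
Cardiac arrest
Arrhythmia
Ventricular tachycardia
Ventricular fibrillation
Ventricular arrhythmia
Electrocardiogram QT prolonged
Bradycardia
Tachycardia
Seizure
Muscle spasms
Tetany
Paraesthesia
Metabolic acidosis
Lactic acidosis
Electrolyte imbalance
Blood lactate dehydrogenase increased
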