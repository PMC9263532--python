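report_id	label	expected	text
p01	bilateral_pos	pos	Diffuse bilateral infiltrates consistent with edema.
p02	bilateral_pos	pos	Bilateral patchy airspace opacities are present.
p03	bilateral_pos	pos	Worsening bilateral consolidation in the lower lobes.
p04	bilateral_pos	pos	There are bibasilar opacities, likely atelectasis versus pneumonia.
p05	bilateral_pos	pos	Extensive airspace disease involving both lungs.
p06	bilateral_pos	pos	Patchy opacities in the right and left lower lobes.
p07	bilateral_pos	pos	Interval increase in bilateral pulmonary opacities.
p08	bilateral_pos	pos	Dense consolidations are seen bilaterally at the bases.
p09	bilateral_pos	pos	New bilateral ground glass opacification noted.
p10	bilateral_pos	pos	Multifocal airspace consolidation in both lungs.
p11	bilateral_pos	pos	Persistent bilateral infiltrates, unchanged from prior.
p12	bilateral_pos	pos	Bilateral perihilar opacities suggest pulmonary edema.
p13	bilateral_pos	pos	Confluent opacities involving the left and right mid lung zones.
p14	bilateral_pos	pos	Increasing bibasilar consolidations compatible with aspiration.
p15	bilateral_pos	pos	Severe bilateral airspace disease throughout.
p16	bilateral_pos	pos	Hazy opacities bilaterally, greater on the right.
n01	negated	neg	No bilateral infiltrates are identified.
n02	negated	neg	No focal infiltrate; lungs clear bilaterally.
n03	negated	neg	Lungs are clear without bilateral opacities.
n04	negated	neg	Negative for bilateral airspace disease.
n05	negated	neg	The previously noted bilateral opacities have resolved.
n06	negated	neg	No evidence of bilateral consolidation.
n07	negated	neg	Without evidence of infiltrate in either lung bilaterally.
n08	negated	neg	Interval resolution of bilateral infiltrates.
n09	negated	neg	Bibasilar opacities have cleared since the prior study.
n10	negated	neg	No new bilateral opacities; stable cardiomegaly.
n11	negated	neg	Clear lungs without bibasilar consolidation.
n12	negated	neg	Negative for infiltrates in both lungs.
n13	negated	neg	No airspace opacities are seen bilaterally.
n14	negated	neg	Lungs clear of infiltrates bilaterally.
n15	negated	neg	No residual bilateral consolidation following diuresis.
n16	negated	neg	Previously seen bilateral infiltrates have now resolved.
c01	clear	neg	
c02	clear	neg	Lungs are clear. Heart size is normal.
c03	clear	neg	No acute cardiopulmonary process.
c04	clear	neg	Clear lungs with normal cardiomediastinal silhouette.
c05	clear	neg	Endotracheal tube in appropriate position. Lungs grossly clear.
c06	clear	neg	Right lower lobe atelectasis; otherwise unremarkable.
c07	clear	neg	Mild pulmonary vascular congestion without focal consolidation.
c08	clear	neg	Stable cardiomegaly. No pleural effusion.
c09	clear	neg	Left basilar opacity likely atelectasis.
c10	clear	neg	Focal right upper lobe infiltrate concerning for pneumonia.
c11	clear	neg	Low lung volumes. No focal airspace disease.
c12	clear	neg	Lines and tubes unchanged. No pneumothorax.
c13	clear	neg	Degenerative changes of the thoracic spine.
c14	clear	neg	Small left pleural effusion with adjacent atelectasis.
c15	clear	neg	Interval extubation. Lungs remain clear bilaterally.
c16	clear	neg	Mild interstitial prominence consistent with volume status.
u01	uncertain	pos	Possible bilateral infiltrates, correlate clinically.
u02	uncertain	pos	Findings may represent bilateral airspace disease.
u03	uncertain	pos	Cannot exclude early bilateral consolidation.
u04	uncertain	pos	Probable bibasilar opacities versus atelectasis.
u05	uncertain	pos	Hazy bilateral opacities, possibly edema.
u06	uncertain	pos	Patchy opacities in both lungs may reflect evolving ARDS.
u07	uncertain	pos	Suspicious for bilateral airspace opacification.
u08	uncertain	pos	Likely bilateral consolidations, infection not excluded.
u09	uncertain	pos	Questionable bilateral infiltrates at the bases.
u10	uncertain	pos	Concerning for bilateral opacities superimposed on chronic changes.
u11	uncertain	pos	Bilateral haziness may represent infiltrates versus overlying soft tissue.
u12	uncertain	pos	Possible bibasilar consolidations, recommend repeat radiograph.
u13	uncertain	pos	Subtle opacities bilaterally, cannot exclude early pneumonia.
u14	uncertain	pos	Equivocal bilateral airspace disease, clinical correlation advised.
u15	uncertain	pos	Probable infiltrates in the right and left bases.
u16	uncertain	pos	Evolving bilateral opacities suggestive of ARDS.
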