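# Class labels and label-revealing terms removed before keyness,
# classification and sentiment scoring
migraine
migraines
clusterhoofdpijn
cluster
hortonse
aura
medicatie
ibuprofen
paracetamol
aspirine
sumatriptan
rizatriptan
triptaan
triptanen
verapamil
lithium
zuurstof
amitriptyline
topiramaat
propranolol
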