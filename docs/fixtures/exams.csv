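exam_id,patient_id,age,psa,facility,biopsy_status,pirads,confirmed,cspca,dominant_zone,exam_iq,iq_source
E0001,P0001,67.2,5.6,I,naive,4,1,1,PZ,,
E0002,P0002,58.9,,II,prev_benign,2,0,0,none,,
E0003,P0003,71.4,9.1,III,unknown,3,1,0,none,optimal,model
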