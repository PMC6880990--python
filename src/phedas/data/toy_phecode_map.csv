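icd9,phecode,phecode_label,exclude_range
296.21,296.2,Depression,295-306
296.31,296.2,Depression,295-306
311,296.2,Depression,295-306
331.0,290.11,Alzheimer's disease,290-294
290.0,290.1,Dementias,290-294
294.8,290.1,Dementias,290-294
299.00,313.3,Autism,295-315
299.01,313.3,Autism,295-315
377.30,377.3,Optic neuritis,377-377.9
377.32,377.3,Optic neuritis,377-377.9
345.90,345,Epilepsy,345-345.9
345.10,345,Epilepsy,345-345.9
365.11,365,Glaucoma,365-365.9
365.9,365,Glaucoma,365-365.9
288.60,288.6,Elevated white blood cell count,288-288.9
288.8,288.6,Elevated white blood cell count,288-288.9
800.00,800,Fracture of skull and face,800-804
802.0,800,Fracture of skull and face,800-804
807.00,807,Fracture of ribs,807-807.9
806.4,807,Fracture of ribs,807-807.9
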