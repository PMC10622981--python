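pt_code,pt_name,hlt,hlgt,soc,smqs,disease_flag,dsm5_domain
PT0001,memory impairment,memory loss,dementia and amnestic condition,nervous system disorders,dementia,false,learning and memory
PT0002,amnesia,memory loss,dementia and amnestic condition,nervous system disorders,dementia,false,learning and memory
PT0003,paramnesia,memory loss,dementia and amnestic condition,nervous system disorders,,false,learning and memory
PT0004,disturbance in attention,attention disturbances,cognitive and attention disorders and disturbances,nervous system disorders,,false,complex attention
PT0005,distractibility,attention disturbances,cognitive and attention disorders and disturbances,nervous system disorders,,false,complex attention
PT0006,speech disorder,speech and language abnormalities,cognitive and attention disorders and disturbances,nervous system disorders,,false,language
PT0007,language disorder,speech and language abnormalities,cognitive and attention disorders and disturbances,nervous system disorders,,false,language
PT0008,word finding difficulty,speech and language abnormalities,cognitive and attention disorders and disturbances,nervous system disorders,,false,language
PT0009,cognitive disorder,cognitive disorders,mental impairment disorders,psychiatric disorders,,false,executive function
PT0010,executive dysfunction,cognitive disorders,mental impairment disorders,psychiatric disorders,,false,executive function
PT0011,judgement impaired,cognitive disorders,mental impairment disorders,psychiatric disorders,,false,executive function
PT0012,apraxia,movement and perception disturbances,cognitive and attention disorders and disturbances,nervous system disorders,,false,perceptual motor function
PT0013,spatial disorientation,movement and perception disturbances,disturbances in thinking and perception,psychiatric disorders,,false,perceptual motor function
PT0014,visuospatial defect,movement and perception disturbances,disturbances in thinking and perception,psychiatric disorders,,false,perceptual motor function
PT0015,inappropriate affect,affect disturbances,mental impairment disorders,psychiatric disorders,,false,social cognition
PT0016,disinhibition,affect disturbances,mental impairment disorders,psychiatric disorders,,false,social cognition
PT0017,confusional state,confusion and disorientation,deliria,psychiatric disorders,,false,complex attention
PT0018,delirium,confusion and disorientation,deliria,psychiatric disorders,,false,complex attention
PT0019,bradyphrenia,thinking disturbances,disturbances in thinking and perception,psychiatric disorders,,false,executive function
PT0020,thinking abnormal,thinking disturbances,disturbances in thinking and perception,psychiatric disorders,,false,executive function
PT0021,mental impairment,cognitive disorders,mental impairment disorders,psychiatric disorders,,false,learning and memory
PT0022,dementia,dementias,dementia and amnestic condition,psychiatric disorders,dementia,true,
PT0023,dementia alzheimer's type,dementias,dementia and amnestic condition,psychiatric disorders,dementia,true,
PT0024,vascular dementia,dementias,dementia and amnestic condition,psychiatric disorders,dementia,true,
PT0025,psychotic disorder,psychoses,disturbances in thinking and perception,psychiatric disorders,,true,
PT0026,schizophrenia,psychoses,disturbances in thinking and perception,psychiatric disorders,,true,
PT0030,nausea,nausea and vomiting symptoms,gastrointestinal motility and defaecation conditions,gastrointestinal disorders,,false,
PT0031,vomiting,nausea and vomiting symptoms,gastrointestinal motility and defaecation conditions,gastrointestinal disorders,,false,
PT0032,diarrhoea,diarrhoea symptoms,gastrointestinal motility and defaecation conditions,gastrointestinal disorders,,false,
PT0033,headache,headaches,neurological disorders nec,nervous system disorders,,false,
PT0034,dizziness,neurological signs,neurological disorders nec,nervous system disorders,,false,
PT0035,fatigue,asthenic conditions,general system disorders nec,general disorders,,false,
PT0036,arthralgia,joint related signs,joint disorders,musculoskeletal disorders,,false,
PT0037,hot flush,vascular disorders nec,vascular disorders nec,vascular disorders,,false,
PT0038,rash,rashes eruptions and exanthems,epidermal and dermal conditions,skin disorders,,false,
PT0039,neutropenia,neutropenias,white blood cell disorders,blood and lymphatic system disorders,,false,
PT0040,alopecia,alopecias,epidermal and dermal conditions,skin disorders,,false,
PT0041,pyrexia,febrile disorders,body temperature conditions,general disorders,,false,
PT0042,insomnia,sleep disturbances,sleep disorders and disturbances,psychiatric disorders,,false,
PT0043,anaemia,anaemias nec,anaemias,blood and lymphatic system disorders,,false,
PT0044,pruritus,pruritus nec,epidermal and dermal conditions,skin disorders,,false,
PT0045,constipation,gastrointestinal atonic conditions,gastrointestinal motility and defaecation conditions,gastrointestinal disorders,,false,
PT0046,cough,coughing and associated symptoms,respiratory disorders nec,respiratory disorders,,false,
PT0047,dyspnoea,breathing abnormalities,respiratory disorders nec,respiratory disorders,,false,
PT0048,oedema peripheral,oedema nec,general system disorders nec,general disorders,,false,
PT0049,back pain,musculoskeletal pain,musculoskeletal disorders nec,musculoskeletal disorders,,false,
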